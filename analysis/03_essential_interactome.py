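"""Integrate BioID2 SILAC enrichment with CSS into an essential interactome.

Simulates KRAS- and NRAS-bait SILAC tables sharing 40 true interactors,
filters to quantifications with >= 2 ratio counts, averages enrichment
across baits, and intersects with a synthetic CSS table (half the
interactors essential).  Also reports the 3-way Venn of the two bait
interactomes (>= 2.0 log2fc) with the essential gene set.
"""

import pathlib

import numpy as np
import pandas as pd

from mmras import interactome as inter, simulate as sim

RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

cfg = sim.SilacSimConfig(
    n_proteins=800, n_true_interactors=40, interactor_log2fc_mean=3.0,
    bait="KRAS_G12V", seed=201,
)
kras_table, truth = sim.simulate_silac_table(cfg)
# NRAS bait shares the true interactors but has independent measurement noise
noise_rng = np.random.default_rng(202)
nras_table = kras_table.assign(
    bait="NRAS_G12V",
    log2fc=kras_table["log2fc"] + noise_rng.normal(0, 0.4, len(kras_table)),
)
tables = {"KRAS_G12V": kras_table, "NRAS_G12V": nras_table}

filtered = [inter.filter_silac(t) for t in tables.values()]
combined = inter.combine_baits(filtered)

interactors = truth.loc[truth["is_interactor"], "protein"].to_numpy()
essential = set(interactors[:20]) | set(truth["protein"].iloc[-30:])
rng = np.random.default_rng(5)
css = pd.DataFrame(
    {
        "gene": truth["protein"],
        "css": np.where(
            truth["protein"].isin(essential), -2.0, rng.normal(0, 0.3, len(truth))
        ),
    }
)

members = inter.essential_interactome(combined, css, css_max=-1.0, fc_min=1.0)
members.to_csv(RESULTS / "essential_interactome.tsv", sep="\t", index=False)
print(
    f"essential interactome: {len(members)} proteins "
    f"(CSS <= -1.0 and combined log2fc >= 1.0) -> essential_interactome.tsv"
)

set_k = set(filtered[0].loc[filtered[0]["log2fc"] >= 2.0, "protein"])
set_n = set(filtered[1].loc[filtered[1]["log2fc"] >= 2.0, "protein"])
venn = inter.venn_intersect(set_k, set_n, essential)
pd.Series(venn["counts"]).to_csv(RESULTS / "venn_counts.tsv", sep="\t", header=False)
print(
    f"Venn regions (KRAS-bait, NRAS-bait, essential): {venn['counts']}; "
    f"triple intersection {len(venn['triple_intersection'])} proteins"
)
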