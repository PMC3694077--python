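"""Derive ADG, ADFI and RFI from raw station records.

ADG is the least-squares slope of biweekly weights on days; ADFI the mean
of a quadratic fit to daily intakes over the test window; RFI the part of
ADFI not explained by growth, body composition and nuisance fixed effects
under a pedigree animal model.  Efficient (LOW-line) pigs end up with
negative RFI.
"""

from rfiwgas import pheno
from rfiwgas.simlines import SimConfig, simulate_dataset

cfg = SimConfig(n_founders=80, n_per_line_per_gen=60, n_generations=5,
                n_snps=300, n_chroms=4, chrom_length_bp=20_000_000,
                selection_fraction=0.3, seed=2)
data = simulate_dataset(cfg)

tab = pheno.derive_phenotypes(data.weights, data.intakes, data.traits, data.pedigree)
tab = pheno.compute_rfi(
    tab, data.pedigree,
    pheno.RfiModelSpec(variance_ratios={"animal": 1.0, "dam": 20.0, "pen": 20.0}),
)

last = cfg.n_generations - 1
g = tab[tab["generation"] == last]
low = g.loc[g["line"] == "LOW", "RFI"].mean()
high = g.loc[g["line"] == "HIGH", "RFI"].mean()
print(tab[["animal_id", "ADG", "ADFI", "BF", "LMA", "RFI"]].head(8).to_string(index=False))
print(f"\ngeneration {last}: mean RFI LOW {low:.3f} vs HIGH {high:.3f} kg/day")
print("the negative LOW-HIGH difference is the realized efficiency gain;")
print("RFI keeps the genetic deviation, so selection response stays visible.")
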