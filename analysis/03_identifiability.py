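"""Profile-likelihood identifiability of the four rates and their composites.

Two demonstrations on synthetic data:

1. A typical well-behaved gene: all four rates and the composites get
   finite 95% confidence intervals.
2. A gene whose nucleoplasmic signal tracks chromatin (k1', k2 fast):
   the individual rates are only bounded from below -- their profiles stay
   flat up to the 1000-fold search limit -- while their ratio k1'/k2 (the
   chromatin-release efficiency) remains sharply identifiable.  This is the
   reparameterization trick: composites are profiled in a model form where
   they appear as coordinates.
"""

from pathlib import Path

import pandas as pd

from exportkinetics import inference
from exportkinetics.model import KineticParams
from exportkinetics.synthetic import (
    GroundTruthGene,
    NoiseSpec,
    gamma_pulse_profile,
    generate_gene_timecourse,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
PARAMS = [
    "k1_prime",
    "k2",
    "k2_prime",
    "k_cyto_deg",
    "chromatin_release_efficiency",
    "export_efficiency",
    "effective_transport",
]


def profile_gene(name: str, params: KineticParams, seed: int) -> pd.DataFrame:
    gene = GroundTruthGene(
        name, params, gamma_pulse_profile(5.0, 25.0, t_peak=20.0), basal_ca=5.0
    )
    sg = generate_gene_timecourse(gene, noise=NoiseSpec(sigma_b=0.15, sigma_t=1.0, seed=seed))
    fit = inference.fit_gene(sg.timecourses, n_starts=80, seed=seed)
    rows = []
    for pname in PARAMS:
        prof = inference.profile_likelihood(sg.timecourses, fit, pname)
        rows.append(
            dict(
                gene=name,
                param=pname,
                truth=getattr(params, pname),
                estimate=prof.estimate,
                ci_lower=prof.ci_lower,
                ci_upper=prof.ci_upper,
                identifiability=prof.identifiability,
            )
        )
    return pd.DataFrame(rows)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    typical = profile_gene(
        "typical", KineticParams(0.4, 0.2, 0.08, 0.012), seed=5
    )
    fast_np = profile_gene(
        "np_tracks_ca", KineticParams(5.0, 5.0, 0.2, 0.02), seed=7
    )
    table = pd.concat([typical, fast_np], ignore_index=True)
    table.to_csv(OUT / "identifiability.tsv", sep="\t", index=False)
    with pd.option_context("display.width", 140):
        print(table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    n_id = (table["identifiability"] == "identifiable").sum()
    print(f"\n{n_id}/{len(table)} profiles identifiable -> {OUT / 'identifiability.tsv'}")
    flat = table[table["identifiability"] != "identifiable"]
    if len(flat):
        print("partially identifiable profiles (all on the constructed fast-np gene):")
        print("  " + ", ".join(flat["gene"] + ":" + flat["param"] +
                               " (" + flat["identifiability"] + ")"))


if __name__ == "__main__":
    main()
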