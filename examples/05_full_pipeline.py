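"""End-to-end screen: landform and land-use models over sex strata.

Runs the whole pipeline on a small synthetic world and prints the
Table-shaped reports: the isolation-by-distance null row, the four
elevation-parameter rows, and the per-class resistance/barrier verdicts.
Artifacts (networks, matrices, screen tables, run manifest) are written to
./landres_demo/.
"""

from landres import PipelineConfig, SyntheticConfig, run_pipeline
from landres.pipeline import screen_to_dataframe

config = PipelineConfig(
    synthetic=SyntheticConfig(grid_rows=30, grid_cols=30, n_individuals=40,
                              n_loci=8, sex_ratio=0.5, beta=2.0, seed=21),
    n_perm=999, seed=21, strata=("all", "males", "females"),
    out_dir="landres_demo",
)
report = run_pipeline(config)

for stratum, result in report["strata"].items():
    print(f"\n=== stratum: {stratum} (n = {result['n']}) ===")
    landform = screen_to_dataframe(result["landform"])
    print("landform screen (simple Mantel r against genetic distance):")
    print(landform[["model", "r_simple", "p_simple", "beats_null"]]
          .to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print("land-use class verdicts (best weight per class):")
    for name, verdict in result["class_verdicts"].items():
        print(f"  {name:<14} {verdict}")
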