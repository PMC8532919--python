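"""Per-animal covariate correlations: does roaming relate to anything?

Builds the wide per-animal table (final cRE, recovered RMR, and the
simulator's generating covariates: base activity rate and roaming share) and
reports all pairwise Pearson correlations with raw two-sided p-values — no
multiple-testing correction, flagged accordingly.  Within the simulation,
cRE should correlate with the generating roaming share and activity rate but
not with the independently generated RMR.
"""

import json
from pathlib import Path

import pandas as pd

from roamkit.stats import correlation_matrix

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "correlations"


def main() -> None:
    re_table = pd.read_csv(ROOT / "scratch" / "tables" / "re_cre.csv",
                           parse_dates=["date"])
    final = re_table[re_table["date"] == re_table["date"].max()]
    wide = final[["animal_id", "cre"]].rename(columns={"cre": "final_cre"})

    truth = json.loads((ROOT / "scratch" / "sim" / "ground_truth.json").read_text())
    cov = pd.DataFrame(
        [
            {"animal_id": a, "base_rate": rec["base_rate"], "roam_share": rec["roam_share"]}
            for a, rec in truth["mice"].items()
        ]
    )
    rmr = pd.read_csv(ROOT / "results" / "metabolic" / "rmr.csv")[["animal_id", "rmr"]]
    wide = wide.merge(cov, on="animal_id").merge(rmr, on="animal_id", how="left")

    OUT.mkdir(parents=True, exist_ok=True)
    wide.to_csv(OUT / "per_animal.csv", index=False)
    res = correlation_matrix(wide.drop(columns=["animal_id"]))
    res.to_csv(OUT / "correlations.csv", index=False)

    print(f"{len(wide)} animals, {len(res)} variable pairs")
    for _, row in res.iterrows():
        print(f"{row.var_a:>10s} ~ {row.var_b:<10s} r = {row.r:+.2f}  p = {row.p:.4f} {row.flag}")
    print("(raw p-values; interpret with caution — no alpha correction)")
    print(f"tables -> {OUT}")


if __name__ == "__main__":
    main()
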