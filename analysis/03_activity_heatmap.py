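"""Colony activity raster: day x 15-min-bin counts of active animals.

An animal is active in a bin when it hit two different antennas within the
quarter hour.  The resulting heatmap shows the dark phase lighting up,
with activity peaks at the light/dark transitions.  CSV goes to results/;
the rendered raster (a convenience figure) goes to scratch/figures/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from roamkit.activity import active_count_heatmap, activity_matrix
from roamkit.rfid_io import parse_event_log

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"
OUT = ROOT / "results" / "activity"
TABLES = ROOT / "scratch" / "tables"  # full heatmap matrices (large)
FIG = ROOT / "scratch" / "figures"
K = 27


def main() -> None:
    log = parse_event_log(SIM / "events.csv", K)
    matrix = activity_matrix(log)
    heat = active_count_heatmap(matrix)

    OUT.mkdir(parents=True, exist_ok=True)
    TABLES.mkdir(parents=True, exist_ok=True)
    heat.to_csv(TABLES / "activity_heatmap.csv")
    long = heat.reset_index().melt(id_vars="date", var_name="bin_start",
                                   value_name="active_count")
    long.to_csv(TABLES / "activity_long.csv", index=False)

    counts = heat.to_numpy()
    dark = np.r_[0:32, 80:96]  # 20:00-08:00 as clock bins
    light = np.r_[32:80]
    print(f"{counts.shape[0]} days x {counts.shape[1]} bins")
    print(f"mean active animals, dark bins : {counts[:, dark].mean():.2f}")
    print(f"mean active animals, light bins: {counts[:, light].mean():.2f}")
    import pandas as pd

    pd.DataFrame(
        {
            "date": heat.index,
            "mean_active_dark": counts[:, dark].mean(axis=1),
            "mean_active_light": counts[:, light].mean(axis=1),
            "peak_active": counts.max(axis=1),
        }
    ).to_csv(OUT / "daily_activity_summary.csv", index=False)

    FIG.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(counts, aspect="auto", cmap="magma", interpolation="nearest")
    ax.set_xlabel("15-min bin of day")
    ax.set_ylabel("day")
    fig.colorbar(im, label="active animals")
    fig.tight_layout()
    fig.savefig(FIG / "activity_heatmap.png", dpi=120)
    print(f"summary -> {OUT}; matrices -> {TABLES}; figure -> {FIG / 'activity_heatmap.png'}")


if __name__ == "__main__":
    main()
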