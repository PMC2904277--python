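#!/usr/bin/env python
"""Trapping comparison of the four canonical beverages at 0.5 L.

Computes initially trapped volume, total absorbable volume and the fast/slow
absorption partition for each preset, plus the hourly circulatory balance of
the HFCS drink.  Writes results/trapping_table.csv and
results/hfcs_timecourse.csv.

Finding: only the 800 mosm/L HFCS drink traps a large volume (0.83 L,
total 1.33 L of isotonic content, 45% back within 2 h, the rest by 4 h);
the 400 mosm/L soup and sucrose drink trap 0.16 L, and the hypotonic
rehydration solution traps nothing.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from osmotrap import analyze_beverage, absorption_timecourse, circulatory_balance
from osmotrap.cli import preset_table_report
from osmotrap.presets import preset_beverage

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table = preset_table_report()
    table.to_csv(OUT / "trapping_table.csv", index=False)
    print(table.drop(columns=["V_d_full_precision", "V_a_full_precision"])
          .to_string(index=False))
    assert table["pass"].all(), "preset table mismatch"

    res = analyze_beverage(preset_beverage("hfcs_softdrink"))
    rows = []
    for t in np.arange(0.0, 4.25, 0.25):
        st = absorption_timecourse(res, float(t))
        rows.append(
            {
                "time_h": t,
                "absorbed_L": st.absorbed,
                "luminal_L": st.luminal,
                "absorbed_fraction": st.absorbed / res.V_a,
                "circulatory_balance_L": circulatory_balance(res, float(t)),
            }
        )
    tc = pd.DataFrame(rows)
    tc.to_csv(OUT / "hfcs_timecourse.csv", index=False)
    at2 = tc.loc[tc.time_h == 2.0].iloc[0]
    print(
        f"\nHFCS drink: V_d={res.V_d:.3f} L, V_a={res.V_a:.3f} L; at 2 h "
        f"{100 * at2.absorbed_fraction:.0f}% absorbed, balance "
        f"{at2.circulatory_balance_L:+.3f} L; at 4 h balance "
        f"{circulatory_balance(res, 4.0):+.3f} L"
    )


if __name__ == "__main__":
    main()
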