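#!/usr/bin/env python
"""Verify the synthetic generator's calibration against its design anchors.

Simulates a year of synthetic ED data with the default profile and prints
the statistics the defaults were calibrated to reproduce: the diurnal
arrival trough/peak, the occupancy trough/peak medians, the crowded-hour
fraction under the top-quartile rule, and the placement of crowding
events in the afternoon/evening.

Usage::

    python scripts/calibrate.py [--seed 7] [--days 365]
"""

import argparse

import numpy as np

import edwarn as ew


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--days", type=int, default=365)
    args = ap.parse_args()

    arr, occ = ew.simulate_ed(args.days, seed=args.seed)
    by_hour_arr = arr.groupby(arr.index.hour)
    med_occ = occ.groupby(occ.index.hour).median()
    scheme = ew.fit_scheme(occ)
    labels = ew.label_hours(occ, scheme)
    crowded_hours = labels[labels == 1].index.hour
    dpo = ew.daily_peak_occupancy(occ)
    crowded_days = (dpo.loc[dpo["complete"], "peak"] >= scheme.threshold).mean()

    print(f"simulated {args.days} days (seed {args.seed})")
    print(f"arrivals : peak hour {by_hour_arr.mean().idxmax()} "
          f"(median {arr[arr.index.hour == 16].median():.0f}, "
          f"max {arr[arr.index.hour == 16].max():.0f}); "
          f"05-06 h median {arr[arr.index.hour.isin([5, 6])].median():.0f}"
          "   [anchors: peak 13 at 16 h, trough 2]")
    print(f"occupancy: 06-08 h median {med_occ.loc[6:8].min():.0f}, "
          f"17-18 h median {med_occ.loc[17:18].max():.0f}, max {occ.max():.0f}"
          "   [anchors: 23 / 74 / 107]")
    print(f"crowding : threshold theta={scheme.threshold:g}, "
          f"{crowded_days * 100:.0f}% of days and "
          f"{labels.mean() * 100:.1f}% of hours crowded"
          "   [anchors: 25% / ~3%]")
    if len(crowded_hours):
        print(f"           crowded hours span {crowded_hours.min()}:00-"
              f"{crowded_hours.max()}:00, modal hour "
              f"{np.bincount(crowded_hours).argmax()}:00"
              "   [anchor: all after 14:00, mode 18:00]")


if __name__ == "__main__":
    main()
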