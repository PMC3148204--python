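#!/usr/bin/env python
"""OPTIONAL external check against the public Framingham teaching subset.

This script is deliberately separate from the test suite and the acceptance
script: it needs network access to download the 40-year follow-up teaching
extract of the Framingham Heart Study (Dupont's textbook website), and the
numbers it checks depend on that external file.  Nothing else in the package
reads or requires it.

Outcome derivation (documented because the file does not define it):
  * event     = death attributed to coronary heart disease within 30 years
                of baseline, i.e. `chdfate == 1` and `followup <= 30 * 365.25`
                days (censoring is deliberately ignored to obtain a single
                binary endpoint with a high prevalence);
  * complete  = rows with non-missing sex, age, bmi, scl (serum cholesterol),
                dbp and sbp;
  * expected:  4658 complete cases, 1403 events (prevalence 0.30), and a
                Youden-optimal cutoff near 0.306 for the six-covariate model.

Run:  python scripts/external_framingham_check.py [--url URL]
"""

from __future__ import annotations

import argparse
import io
import sys
import urllib.request

import numpy as np
import pandas as pd

from decurve import fit_logistic_model, roc_points, youden_cutoff

DEFAULT_URL = "http://biostat.mc.vanderbilt.edu/dupontwd/wddtext/data/2.20.Framingham.csv"
COVARIATES = ["sex", "age", "bmi", "scl", "dbp", "sbp"]


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--url", default=DEFAULT_URL)
    args = parser.parse_args()

    print(f"downloading {args.url} ...", file=sys.stderr)
    raw = urllib.request.urlopen(args.url, timeout=60).read()
    table = pd.read_csv(io.BytesIO(raw))
    table.columns = [c.lower() for c in table.columns]

    death_col = "chdfate"
    time_col = next(c for c in table.columns if "follow" in c)
    table["event"] = (
        (table[death_col] == 1) & (table[time_col] <= 30 * 365.25)
    ).astype(int)

    complete = table.dropna(subset=COVARIATES + ["event"])
    n, events = len(complete), int(complete["event"].sum())
    print(f"complete cases: n = {n} (expected 4658)")
    print(f"events: {events} (expected 1403), prevalence = {events / n:.4f}")

    fitted = fit_logistic_model(
        complete[COVARIATES].to_numpy(float), complete["event"].to_numpy(int)
    )
    op = youden_cutoff(roc_points(fitted))
    print(
        f"Youden-optimal cutoff p_c = {op.cutoff:.3f} (expected ~0.306), "
        f"sens = {op.sensitivity:.3f}, spec = {op.specificity:.3f}"
    )
    return 0


if __name__ == "__main__":
    sys.exit(main())
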