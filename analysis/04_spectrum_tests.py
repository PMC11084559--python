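#!/usr/bin/env python
"""Test glucose and strain effects on the mutational spectrum.

Runs the Type-II likelihood-ratio tests: the joint multinomial model over
all 8 categories (7 df per term) and the per-category binomial logistic
models (1 df per term).  Writes results/spectrum_tests.json and prints
which categories shift with glucose or strain.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from fluctspec.spectrum_models import (
    CATEGORIES,
    fit_binomial_class,
    tabulate_spectrum,
    type2_tests_multinomial,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    calls = pd.read_csv(args.results / "calls.csv", keep_default_na=False)
    table = tabulate_spectrum(calls)

    multinomial = type2_tests_multinomial(table)
    print("Joint multinomial model (all categories):")
    for t in multinomial:
        print(f"  {t.term:>12}: chi2({t.df}) = {t.lr_stat:.2f}, p = {t.p:.3f}")

    per_class = {cat: fit_binomial_class(table, cat) for cat in CATEGORIES}
    print("Per-category logistic models (significant terms, p < 0.05):")
    any_sig = False
    for cat, tests in per_class.items():
        for t in tests:
            if t.p == t.p and t.p < 0.05:
                any_sig = True
                print(f"  {cat:>10} {t.term}: chi2(1) = {t.lr_stat:.2f}, "
                      f"p = {t.p:.3f}")
    if not any_sig:
        print("  none")

    payload = {
        "multinomial": [t.__dict__ for t in multinomial],
        "per_class": {cat: [t.__dict__ for t in tests]
                      for cat, tests in per_class.items()},
    }
    with open(args.results / "spectrum_tests.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


if __name__ == "__main__":
    main()
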