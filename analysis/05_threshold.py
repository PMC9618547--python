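"""Threshold analysis: AVXS-101 acquisition price vs willingness-to-pay.

Solves, for each willingness-to-pay value, the one-off acquisition
price at which the ICER of AVXS-101 versus standard of care equals the
threshold, using the closed-form affine price-ICER relation verified
by a model re-run.  Where no non-negative price satisfies the
threshold the table reports an empty entry.
"""

import pathlib

import numpy as np

from smacea import base_case_spec, threshold_curve
from smacea.cea import threshold_price

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "threshold"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = base_case_spec()
    grid = list(np.arange(5e5, 7.01e6, 250000.0))
    table = threshold_curve(spec, grid)
    table.to_csv(OUT / "threshold_prices.csv", index=False)

    for wtp in (500000.0, 1000000.0, 1750000.0):
        raw = threshold_price(spec, wtp, allow_negative=True)
        if raw is None or raw < 0:
            print(f"WTP {wtp:>12,.0f}: not cost-effective at any "
                  f"non-negative price (closed form {raw:,.0f})")
        else:
            print(f"WTP {wtp:>12,.0f}: threshold price {raw:,.0f}")
    print(f"Threshold curve written to {OUT}")


if __name__ == "__main__":
    main()
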