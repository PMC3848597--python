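"""Generate the default synthetic sales-level survey.

Emulates a low-volume anti-malarial/RDT market surveyed at two visits two
weeks apart: 39 wholesale and 66 retail outlets, a catalogue of 8
anti-malarials and 3 RDTs, zero-inflated negative-binomial sales, wholesale
under-recall, retail volume-dependent under-recall, stated-vs-counted stock
error, and item nonresponse.  Writes products.csv, survey.csv and the
test-only truth.csv under results/data/.

Usage: python analysis/01_simulate_market.py [--seed N] [--out DIR]
"""

import argparse
import json
from pathlib import Path

from slsagree.synthetic import MarketConfig, MeasurementConfig, generate_survey


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/data")
    args = ap.parse_args()

    market = MarketConfig(seed=args.seed)
    meas = MeasurementConfig()
    manifest = generate_survey(market, meas, args.out)
    print(f"wrote {manifest['n_records']} survey records "
          f"({manifest['n_products']} products) to {args.out}")
    print(json.dumps(manifest, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
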