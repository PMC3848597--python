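"""Between-method agreement on the simulated survey.

Runs the full comparison pipeline — AETD standardization, stock-flow RA
estimation, negative-RA and nonresponse exclusions, per-outlet totals,
outlier screen, Bland-Altman statistics — separately for each outlet level
x product category, and writes the results tables, the response-accounting
table, the exclusion log and the four mean-difference plots under
results/analysis/.

Usage: python analysis/02_agreement_analysis.py [--data DIR] [--out DIR]
"""

import argparse
from pathlib import Path

from slsagree import io as slsio
from slsagree.agreement import ba_plot
from slsagree.reporting import analyze_survey, render_table1


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results/analysis")
    ap.add_argument("--outlier-k", type=float, default=3.0)
    args = ap.parse_args()

    data, out = Path(args.data), Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    specs = slsio.read_products_csv(data / "products.csv")
    records = slsio.read_survey_csv(data / "survey.csv")
    run = analyze_survey(records, specs, outlier_k=args.outlier_k)

    m = run.manifest
    print(f"records read {m.n_records_read}, analyzed {m.n_records_analyzed}, "
          f"excluded {m.n_records_excluded} {m.exclusions_by_reason}")
    run.results_frame().to_csv(out / "results.csv", index=False)
    render_table1(run.accounting).to_csv(out / "accounting.csv")
    slsio.write_exclusions_csv(run.exclusions, out / "exclusions.csv")

    for (level, cat), sr in sorted(run.strata.items()):
        for variant, res in sr.results.items():
            tag = "" if variant == "main" or len(sr.results) == 1 else "_with_outliers"
            name = f"ba_{level}_{cat}{tag}.png"
            ba_plot(res, sr.diffs[variant], str(out / name), unit=sr.unit,
                    title=f"{level} {cat} ({variant})")
            flag = "" if res.r_status != "ok" or res.r_p >= 0.05 else \
                "  <- proportional bias"
            print(f"{level:9s} {cat:12s} {variant:4s} n={res.n:3d} "
                  f"bias={res.bias:6.2f} LoA=({res.loa[0]:6.2f},{res.loa[1]:6.2f}) "
                  f"r={res.r if res.r is None else round(res.r, 2)}{flag}")
        if sr.flagged_outliers:
            ids = ", ".join(p.outlet_id for p in sr.flagged_outliers)
            print(f"  outlier outlet(s) excluded from the main variant: {ids}")
    print(f"tables and plots written to {out}")


if __name__ == "__main__":
    main()
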