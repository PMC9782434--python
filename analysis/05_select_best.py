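"""Apply the selection flow and report the best classifier per experiment.

Reads the benchmark artifacts (from 04_benchmark_classifiers.py), applies
the ordered 80% gates (accuracy -> recall -> precision), computes the
goodness index and category for the survivors, and picks the
lowest-goodness classifier per experiment.  Gate-blocked cells are
rendered "/" in the exported report.
"""

from pathlib import Path

from posturebench.pipeline import load_bench_dir
from posturebench.selection import evaluate_bench

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    results = load_bench_dir(OUT / "bench")
    report = evaluate_bench(results)
    frame = report.to_frame()
    frame.to_csv(OUT / "selection_report.csv", index=False)

    print("selection report (gates at 80%, '/' = blocked):")
    print(frame.to_string(index=False))

    print("\nbest classifier per experiment (lowest goodness index):")
    for exp, name in report.best.items():
        if name is None:
            print(f"  {exp:8s} -> none passed all three gates")
            continue
        row = next(r for r in report.rows
                   if r.experiment == exp and r.classifier == name)
        print(f"  {exp:8s} -> {name}  ACC {row.metrics.acc:.1f}%  "
              f"G {row.metrics.goodness:.2f} ({row.category.value})  "
              f"AUC {row.metrics.auc:.2f}")


if __name__ == "__main__":
    main()
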