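"""Cross-validate the 13 classifier variants on the 4 experiments.

Reads results/features.csv (from 03_extract_features.py), runs the
52-combination benchmark with subject-grouped stratified 50-fold CV
(leave-one-subject-out for the neural network), and writes per-combination
confusion matrices and pooled out-of-fold scores under results/bench/.
"""

import time
from pathlib import Path

import pandas as pd

from posturebench.pipeline import RunConfig, run_bench
from posturebench.selection import compute_metrics

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    config = RunConfig.from_yaml(ROOT / "configs" / "paper_protocol.yaml")
    table = pd.read_csv(ROOT / "results" / "features.csv")
    t0 = time.time()
    results = run_bench(config, table, out_dir=ROOT / "results" / "bench")
    print(f"{len(results)} classifier-experiment combinations "
          f"in {time.time() - t0:.0f} s -> results/bench/\n")

    acc = pd.DataFrame({
        "experiment": [r.experiment for r in results],
        "classifier": [r.classifier for r in results],
        "ACC": [round(compute_metrics(r.confusion).acc, 1)
                for r in results],
    }).pivot(index="classifier", columns="experiment", values="ACC")
    print("pooled cross-validated accuracy (%):")
    print(acc.to_string())


if __name__ == "__main__":
    main()
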