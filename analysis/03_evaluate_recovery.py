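"""Score the pipeline's output against the planted ground truth.

Reports planted-peak recovery, observed FDR, ChAR-gene pair assignment,
module recovery (ARI), motif and reference-peakset readouts; writes
results/recovery_metrics.json.
"""

import argparse
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "scripts"))

from acceptance import round_trip_metrics  # noqa: E402
from charflow.pipeline import RunConfig, run_pipeline  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--bundle", type=Path, default=Path("results/fixture"))
    ap.add_argument("--pipeline-out", type=Path, default=Path("results/pipeline_eval"))
    ap.add_argument("--out", type=Path, default=Path("results/recovery_metrics.json"))
    args = ap.parse_args()

    truth = json.loads((args.bundle / "ground_truth.json").read_text())
    config = RunConfig.from_yaml(args.bundle / "run_config.yaml")
    results = run_pipeline(config, args.pipeline_out)
    metrics = round_trip_metrics(truth, results)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(metrics, indent=1, sort_keys=True))
    for name, rec in sorted(metrics.items()):
        print(f"{name}: value={rec['value']:.4g} n={rec['n']}")


if __name__ == "__main__":
    main()
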