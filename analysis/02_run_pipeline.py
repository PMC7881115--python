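"""Run the full ChAR analysis on the simulated bundle.

Executes QC, consensus merging, differential accessibility for all four
comparisons, accessibility-module clustering, motif enrichment, RNA DEG +
GSEA, and ChAR-gene integration; tables land under results/pipeline/.
"""

import argparse
from pathlib import Path

from charflow.pipeline import RunConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--bundle", type=Path, default=Path("results/fixture"))
    ap.add_argument("--out", type=Path, default=Path("results/pipeline"))
    args = ap.parse_args()

    config = RunConfig.from_yaml(args.bundle / "run_config.yaml")
    results = run_pipeline(config, args.out)
    manifest = results["manifest"]
    print(f"completed stages: {', '.join(manifest['stages'])}")
    print(f"consensus ChARs: {manifest['n_chars']}")
    for comp, table in results["atac_differential"].items():
        n_sig = int(((table.q_value < 0.05) & (table.log2FC.abs() >= 1)).sum())
        print(f"  {comp}: {n_sig} differential ChARs (|log2FC|>=1, q<0.05)")
    print(f"DEGs A_L vs V_L: {len(results['degs']['up'])} up, "
          f"{len(results['degs']['down'])} down")
    print(results["gsea"].to_string(index=False))


if __name__ == "__main__":
    main()
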