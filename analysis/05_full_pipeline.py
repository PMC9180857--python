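"""One-command reproduction: simulate -> indices -> diversity -> stats.

Runs the same end-to-end pipeline as `soilecotox run`, writing the complete
report bundle and the manifest that reproduces it byte-for-byte.
"""

import argparse

from soilecotox.cli_io import PipelineConfig, run_pipeline

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
args = parser.parse_args()

result = run_pipeline(PipelineConfig(seed=args.seed, outdir="results/pipeline"))
print(f"pipeline bundle ({len(result.files)} files) in results/pipeline/:")
for name, path in sorted(result.files.items()):
    print(f"  {path.name}")
ifx = result.index_report.query("index == 'IF_X'")
print(f"index report: {len(result.index_report)} rows, "
      f"{ifx['variable'].nunique()} variables with xenobiotic influence factors")
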