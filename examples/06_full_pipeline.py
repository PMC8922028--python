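"""Run the complete pipeline and write a reproducible report bundle.

One call executes simulation (or file loading), condition tabulation,
sensitivity contrasts, preprocessing, two-tier MANOVA, IBR scoring and
the IBR ANOVA, writing every intermediate table plus a decision log.
"""

import json
from pathlib import Path

import coralstress as cs

out = Path("scratch/pipeline_demo")
bundle = cs.run_pipeline(cs.RunConfig(seed=42, output_dir=out, on_shortfall="all"))

print("bundle files:")
for f in sorted(out.iterdir()):
    print(f"  {f.name}")
print("\nsummary:")
print(json.dumps(bundle["summary"], indent=2))
print("\nIBR ANOVA on this run:")
for term, r in bundle["ibr_anova"].items():
    print(f"  {term:25s} F = {r.statistic:.3f}  p = {r.pvalue:.3f}")

# Rerunning with the same seed reproduces every file byte-for-byte; the
# decisions.log records each runtime choice (transforms applied, tiers,
# flagged discrepancies) so an analysis can be audited afterwards.
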