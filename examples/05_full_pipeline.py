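"""Run the whole pipeline on a synthetic landscape with known truth.

Climate → bioclim → occurrence cleaning → replicate maxent fits →
pruning → presence-mean threshold → river overlay → population
estimate, all reproducible from one master seed.  Artifacts land in
./pipeline_run/.
"""

import json

from riversdm.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=0, replicates=5, background_n=2000,
                     synth_occurrences=200, min_order=1)
summary = run_pipeline(cfg, "pipeline_run")

print(json.dumps(summary, indent=2))
print("\nmean_test_auc near 1 means the fitted habitat map separates "
      "presences from background; the estimate extrapolates the "
      "simulated survey densities (truth: 0.5 birds/km) over the "
      "suitable river length the model recovered.")
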