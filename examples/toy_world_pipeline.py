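"""End-to-end run on a synthetic two-basin world with a canal.

Builds a deterministic toy ocean (two basins split by a meridional
continent, canal at the isthmus, six coastal regions), computes the three
distance matrices, standardizes them to risks and combines them.
"""

from searisk import PipelineConfig, run_pipeline

config = PipelineConfig(outdir="scratch/toy_run", synthetic={"noise_sd": 0.0}, seed=0)
result = run_pipeline(config)

combined = result["matrices"]["combined_risk"].df
print("Combined source-destination risk (0 = self, up to 3 = most similar/closest):")
print(combined.round(3).to_string())
print()
print("Rounding caps M used by risk = 1 - d/M:")
for name, cap in result["caps"].items():
    print(f"  {name}: {cap}")
print()
print("Each off-diagonal entry sums environmental-similarity, voyage-duration")
print("and voyage-path risk for that region pair; higher means a riskier route.")
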