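"""Run the whole pipeline end to end into ./scratch/demo_run.

Equivalent to `hipmorph run-all --seed 0 --out scratch/demo_run` with a
lighter permutation count. Outputs: NIfTI phantom images, per-muscle
agreement and reliability tables, volumes, 101-node MFI profiles (whole
muscles plus Gmed/Gmin subregions), the adjusted regression table, the SPM
t-curve and a manifest with file digests.
"""
import pandas as pd

from hipmorph import RunConfig, run_pipeline

cfg = RunConfig(seed=0, n_perm=1000)
out = run_pipeline(cfg, "scratch/demo_run")
print(f"outputs in {out}:")

vols = pd.read_csv(out / "volumes.csv")
print("\nmuscle volumes (mm^3):")
print(vols.to_string(index=False))

reg = pd.read_csv(out / "regression.csv")
cols = ["muscle", "adjusted_difference_mm3", "ci_low", "ci_high", "p_value"]
print("\nadjusted group differences on the synthetic cohort:")
print(reg[cols].round(1).to_string(index=False))
# Rerunning with the same config reproduces every file byte-for-byte; change
# the seed to draw a new phantom, rater perturbation and cohort.
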