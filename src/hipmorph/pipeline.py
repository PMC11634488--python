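"""End-to-end orchestration: simulate -> agreement -> morphometry -> stats.

A run is fully determined by its :class:`RunConfig` (which round-trips to
YAML losslessly) — rerunning with the same config and seed reproduces every
numeric output bit-for-bit. Images are written as uncompressed NIfTI and
tables as CSV; a manifest JSON records the config, its hash and SHA-256
digests of every output file.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement, cohort_stats, dixon_io, morphometry, phantom

__all__ = ["RunConfig", "run_pipeline", "ConfigError"]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All knobs for one pipeline run; every field has a documented default.

    seed: master seed; each stage derives its own stream from it.
    phantom_noise_sd: Dixon intensity noise as a fraction of in-muscle signal.
    rater_flip_prob: boundary-flip probability of the simulated second rater.
    n_symptomatic / n_control: synthetic cohort group sizes.
    spm_method: 'permutation' or 'rft'; n_perm: permutation count; alpha:
    family-wise significance level.
    n_profiles_per_group / profile_noise_sd / profile_group_effect: the
    simulated per-subject MFI curves entering the SPM stage.
    """

    seed: int = 0
    phantom_noise_sd: float = 0.02
    rater_flip_prob: float = 0.2
    n_symptomatic: int = 180
    n_control: int = 48
    spm_method: str = "permutation"
    n_perm: int = 2000
    alpha: float = 0.05
    n_profiles_per_group: int = 20
    profile_noise_sd: float = 0.03
    profile_group_effect: float = 0.0

    def validate(self) -> None:
        if not 0 <= self.rater_flip_prob <= 1:
            raise ConfigError("rater_flip_prob must be in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.spm_method not in ("permutation", "rft"):
            raise ConfigError(f"unknown spm_method {self.spm_method!r}")
        if self.n_perm < 100:
            raise ConfigError("n_perm must be at least 100")
        if min(self.n_symptomatic, self.n_control, self.n_profiles_per_group) < 2:
            raise ConfigError("group sizes must be at least 2")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def stage_simulate(config: RunConfig, outdir: Path) -> dict:
    spec = phantom.default_phantom_spec(seed=config.seed, noise_sd=config.phantom_noise_sd)
    dixon, mask = phantom.generate_phantom(spec)
    rater2 = phantom.perturb_mask(mask, config.rater_flip_prob, seed=config.seed + 1)
    dixon_io.write_dixon_pair(dixon, outdir / "fat.nii", outdir / "water.nii")
    dixon_io.write_label_mask(mask, outdir / "mask.nii")
    dixon_io.write_label_mask(rater2, outdir / "mask_rater2.nii")
    return {"dixon": dixon, "mask": mask, "rater2": rater2}


def stage_agreement(mask, rater2, outdir: Path) -> pd.DataFrame:
    rows = []
    for label, (muscle, side) in sorted(mask.label_map.items()):
        rep = agreement.overlap_metrics(mask, rater2, label)
        rows.append({"muscle": muscle, "side": side, **rep.as_dict()})
    df = pd.DataFrame(rows)

    # volume reliability across muscles, rater 1 vs rater 2
    v1 = np.array([morphometry.muscle_volume(mask, l).volume_mm3
                   for l in sorted(mask.label_map)])
    v2 = np.array([morphometry.muscle_volume(rater2, l).volume_mm3
                   for l in sorted(mask.label_map)])
    icc = agreement.icc_2_1(np.column_stack([v1, v2]))
    ba = agreement.bland_altman(v1, v2)
    es = agreement.error_stats(v1, v2)
    rel = pd.DataFrame([{
        "measure": "volume_mm3", "icc_2_1": icc.icc,
        "icc_ci_low": icc.ci_low, "icc_ci_high": icc.ci_high,
        "ba_bias": ba.bias, "ba_loa_low": ba.loa_low, "ba_loa_high": ba.loa_high,
        "mae": es.mae, "rmse": es.rmse, "pearson_r": es.pearson_r,
        "r_squared": es.r_squared,
    }])
    _write_csv(df, outdir / "agreement.csv")
    _write_csv(rel, outdir / "reliability.csv")
    return df


def stage_morphometry(dixon, mask, outdir: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    vol_rows, prof_rows = [], []
    for label, (muscle, side) in sorted(mask.label_map.items()):
        rec = morphometry.muscle_volume(mask, label)
        vol_rows.append({"muscle": muscle, "side": side, "label": label,
                         "volume_mm3": rec.volume_mm3})
        prof = morphometry.mfi_profile(dixon, mask, label)
        for node, val in enumerate(prof.nodes):
            prof_rows.append({"muscle": muscle, "side": side,
                              "subregion": "whole", "node": node, "mfi": val})
        if muscle in morphometry.SUBREGION_SCHEMES:
            sub = morphometry.split_subregions(mask, label)
            for sl, (sub_name, s) in sorted(sub.label_map.items()):
                sprof = morphometry.mfi_profile(dixon, sub, sl)
                region = sub_name.split("_", 1)[1]
                for node, val in enumerate(sprof.nodes):
                    prof_rows.append({"muscle": muscle, "side": side,
                                      "subregion": region, "node": node,
                                      "mfi": val})
    volumes = pd.DataFrame(vol_rows)
    profiles = pd.DataFrame(prof_rows)
    _write_csv(volumes, outdir / "volumes.csv")
    _write_csv(profiles, outdir / "profiles.csv")
    return volumes, profiles


def stage_stats(config: RunConfig, outdir: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    cohort_spec = phantom.CohortSpec(
        n_symptomatic=config.n_symptomatic, n_control=config.n_control,
        seed=config.seed + 2,
    )
    cohort = phantom.generate_cohort(cohort_spec)
    cohort = cohort_stats.select_limbs(cohort, seed=config.seed + 3)
    _write_csv(cohort, outdir / "cohort.csv")

    reg_rows = []
    for muscle in phantom.MUSCLES:
        res = cohort_stats.volume_regression(cohort, muscle)
        reg_rows.append({
            "muscle": muscle,
            "adjusted_difference_mm3": res.adjusted_difference_mm3,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
            "p_value": res.p_value,
            "interaction_p": res.interaction_p,
            "interaction_retained": res.interaction_retained,
            "percent_difference": res.percent_difference,
            "n_symptomatic": res.n_symptomatic, "n_control": res.n_control,
        })
    regression = pd.DataFrame(reg_rows)
    _write_csv(regression, outdir / "regression.csv")

    base = phantom.MFIProfile("quadratic", (0.25, -0.4, 0.3))
    prof_a = phantom.simulate_profile_group(
        base, config.n_profiles_per_group, config.profile_noise_sd,
        seed=config.seed + 4, effect=config.profile_group_effect,
    )
    prof_b = phantom.simulate_profile_group(
        base, config.n_profiles_per_group, config.profile_noise_sd,
        seed=config.seed + 5,
    )
    spm = cohort_stats.spm_ttest(
        prof_a, prof_b, alpha=config.alpha, method=config.spm_method,
        n_perm=config.n_perm, seed=config.seed + 6,
    )
    spm_df = pd.DataFrame({
        "node": np.arange(len(spm.t)), "t": spm.t,
        "t_crit": spm.t_crit, "alpha": spm.alpha, "method": spm.method,
    })
    _write_csv(spm_df, outdir / "spm.csv")
    return regression, spm_df


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Run all stages into ``outdir`` and write a manifest.

    Any stage failure is re-raised annotated with the stage name. Outputs are
    deterministic functions of (config, seed).
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    timings: dict[str, float] = {}

    def timed(name, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(*args)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = time.perf_counter() - t0
        log.info("stage %s done in %.2fs", name, timings[name])
        return result

    sim = timed("simulate", stage_simulate, config, out)
    timed("agreement", stage_agreement, sim["mask"], sim["rater2"], out)
    timed("morphometry", stage_morphometry, sim["dixon"], sim["mask"], out)
    timed("stats", stage_stats, config, out)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.iterdir())
            if p.suffix in (".csv", ".nii", ".yaml") and p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
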