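"""End-to-end orchestration: simulate or ingest, analyse, report.

``run_pipeline`` runs simulate -> per-locus frequencies -> ancestry ->
burden test and writes every stage's table plus a manifest (seeds, config
hash, library versions) so a run can be re-executed identically. Stage
failures abort with the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, burden
from .ancestry import AdmixtureModel
from .synthdata import (
    CohortConfig,
    gen_aims,
    gen_cohort,
    gen_panel,
    gen_thetas,
    study_loci,
    write_phenotypes,
    write_vcf,
)

log = logging.getLogger("rareburden")


@dataclass
class RunConfig:
    """Pipeline configuration (simulation mode)."""

    seed: int = 0
    n_cases: int = 264
    n_controls: int = 218
    missing_rate: float = 0.02
    n_perm: int = 10_000
    alternative: str = "greater"
    zero_policy: str = "drop"
    similar_abs_tol: float = 0.0
    aims_markers: int = 102
    aims_delta: float = 0.733
    theta_mean: float = 0.70
    theta_sd: float = 0.08

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                log.info("stage %s: start", name)
                out = fn(*args, **kwargs)
                log.info("stage %s: done", name)
                return out
            except Exception as e:  # annotate with the failing stage
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e

        return wrapped

    return deco


def run_pipeline(config: RunConfig, outdir: str | os.PathLike) -> dict:
    """Run the full simulated-cohort analysis; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _derive_seeds(config.seed)

    cohort = _simulate(config, seeds, outdir)
    pairs = _freqs(cohort, outdir)
    ancestry_frame = _ancestry(config, cohort, seeds, outdir)
    result = _burden(config, pairs, seeds, outdir)

    report = [
        f"rareburden {__version__} pipeline report",
        f"cohort: {cohort.n_cases} cases / {cohort.n_controls} controls, "
        f"{cohort.n_loci} loci, missing rate {config.missing_rate}",
        "",
        result.summary(),
        "",
        "ancestry (mean theta): "
        f"cases {ancestry_frame.loc[ancestry_frame.status == 'case', 'theta'].mean():.3f}, "
        f"controls {ancestry_frame.loc[ancestry_frame.status == 'control', 'theta'].mean():.3f}",
    ]
    (outdir / "report.txt").write_text("\n".join(report) + "\n")

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "stage_seeds": seeds,
        "outputs": sorted({p.name for p in outdir.iterdir()} | {"manifest.json"}),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _derive_seeds(seed: int) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    return {
        name: int(rng.integers(0, 2**31 - 1))
        for name in ("cohort", "panel", "thetas", "aims", "permutation")
    }


@_stage("simulate")
def _simulate(config: RunConfig, seeds: dict, outdir: Path):
    cohort_cfg = CohortConfig(
        n_cases=config.n_cases,
        n_controls=config.n_controls,
        loci=study_loci(),
        missing_rate=config.missing_rate,
        seed=seeds["cohort"],
    )
    cohort = gen_cohort(cohort_cfg)
    write_vcf(cohort, outdir / "cohort.vcf")
    write_phenotypes(cohort, outdir / "phenotypes.tsv")
    log.info("simulate: %d samples x %d loci", cohort.n_samples, cohort.n_loci)
    return cohort


@_stage("freqs")
def _freqs(cohort, outdir: Path):
    pairs = burden.locus_freq_table(cohort)
    burden.freq_frame(pairs).to_csv(outdir / "locus_freqs.tsv", sep="\t", index=False)
    log.info("freqs: %d loci", len(pairs))
    return pairs


@_stage("ancestry")
def _ancestry(config: RunConfig, cohort, seeds: dict, outdir: Path) -> pd.DataFrame:
    panel = gen_panel(config.aims_markers, config.aims_delta, seed=seeds["panel"])
    thetas = gen_thetas(
        cohort.n_samples, config.theta_mean, config.theta_sd, seed=seeds["thetas"]
    )
    aims = gen_aims(thetas, panel, seed=seeds["aims"])
    panel.write(outdir / "aims_panel.tsv")
    model = AdmixtureModel(aims, panel, sample_ids=cohort.sample_ids, is_case=cohort.is_case)
    frame = model.fit().to_frame()
    frame.to_csv(outdir / "ancestry.tsv", sep="\t", index=False)
    log.info("ancestry: %d individuals estimated", len(frame))
    return frame


@_stage("burden")
def _burden(config: RunConfig, pairs, seeds: dict, outdir: Path):
    test = burden.BurdenTest(pairs, similar_abs_tol=config.similar_abs_tol)
    result = test.fit(
        n_perm=config.n_perm,
        seed=seeds["permutation"],
        alternative=config.alternative,  # type: ignore[arg-type]
        zero_policy=config.zero_policy,  # type: ignore[arg-type]
    )
    pd.DataFrame([{
        "w_plus": result.w_plus,
        "n_nonzero": result.n_nonzero,
        "empirical_p": result.empirical_p,
        "n_perm": result.n_perm,
        "alternative": result.alternative,
        "zero_policy": result.zero_policy,
        "case_higher": result.direction_tally.get("case_higher"),
        "control_higher": result.direction_tally.get("control_higher"),
        "similar": result.direction_tally.get("similar"),
    }]).to_csv(outdir / "burden.tsv", sep="\t", index=False)
    return result
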