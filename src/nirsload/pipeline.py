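"""End-to-end study runner: simulate -> preprocess -> features -> group stats
-> classification with permutation nulls, with a manifest recording the
configuration hash and seed so any stage can be reproduced in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import yaml

from .classify import classification_study
from .features import cohort_feature_matrix
from .group_stats import compare_cells
from .io import PipelineConfig, write_cohort, write_feature_matrix
from .synthetic.simulate import simulate_cohort

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def config_hash(config: PipelineConfig) -> str:
    blob = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_study(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline and persist every declared artifact.

    Any stage failure raises :class:`StageError` naming the stage; artifacts
    produced by earlier stages remain on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "stages": {},
        "files": [],
    }

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # persist partial outputs, then abort
            _write_manifest(out, manifest)
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        manifest["stages"][name] = round(dt, 3)
        logger.info("stage %s finished in %.2f s", name, dt)
        return result

    cohort = _stage("simulate", lambda: simulate_cohort(config.study, config.seed))
    if config.write_recordings:
        files = _stage("write_cohort", lambda: write_cohort(cohort, out / "cohort"))
        manifest["files"] += [str(p.relative_to(out)) for p in files]

    matrix = _stage(
        "features",
        lambda: cohort_feature_matrix(
            cohort, config.preprocess, use_ssr=config.use_ssr,
            statistic=config.statistic,
        ),
    )
    write_feature_matrix(matrix, out / "features.csv")
    manifest["files"].append("features.csv")

    def _stats():
        frames = [compare_cells(matrix, "skill", config=config.stats)]
        for group in ("student", "attending"):
            frames.append(
                compare_cells(matrix, "load", group=group, config=config.stats)
            )
        import pandas as pd

        return pd.concat(frames, ignore_index=True)

    stats_df = _stage("group_stats", _stats)
    stats_df.to_csv(out / "stats.csv", index=False, float_format="%.9g")
    manifest["files"].append("stats.csv")

    reports = {}
    for target in ("skill", "load"):
        rep = _stage(
            f"classify_{target}",
            lambda t=target: classification_study(
                matrix,
                t,
                config.classifier,
                episode=config.episode,
                separation_cm=config.class_cm,
                group="student" if t == "load" else None,
            ),
        )
        rep.to_json(out / f"report_{target}.json")
        manifest["files"].append(f"report_{target}.json")
        reports[target] = rep

    _write_manifest(out, manifest)
    return {
        "cohort": cohort,
        "matrix": matrix,
        "stats": stats_df,
        "reports": reports,
        "manifest": manifest,
    }


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if "manifest.json" not in manifest["files"]:
        manifest["files"].append("manifest.json")
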