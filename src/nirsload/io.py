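"""Cohort interchange format and pipeline configuration.

A cohort directory contains ``layout.csv``, ``schedule.json``, ``tlx.csv``,
``ground_truth.json`` (scalar per-subject truth only), and per subject
``od_<id>.csv`` (long format: time_s, channel_id, wavelength_nm, delta_od)
and ``motion_<id>.csv``.  All floating point is written with 9 significant
digits, which makes writes byte-reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import ClassifierConfig
from .constants import WAVELENGTHS
from .features import ActivationMatrix
from .group_stats import StatsConfig
from .preprocess import PreprocessConfig
from .synthetic.layout import ChannelLayout, LayoutConfig
from .synthetic.simulate import (
    Cohort,
    Episode,
    PhysioConfig,
    ProtocolSchedule,
    RawRecording,
    StudyConfig,
    TLXLink,
    TLXRecord,
)

FLOAT_FMT = "%.9g"


class SchemaError(ValueError):
    """Interchange files missing or inconsistent."""


# ---------------------------------------------------------------------------
# cohort writer / reader
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    p = out / "layout.csv"
    cohort.layout.to_frame().to_csv(p, index=False, float_format=FLOAT_FMT)
    written.append(p)

    p = out / "schedule.json"
    with open(p, "w") as fh:
        json.dump(
            {
                "fs": cohort.schedule.fs,
                "episodes": [
                    {"name": e.name, "start_s": e.start_s, "end_s": e.end_s}
                    for e in cohort.schedule.episodes
                ],
            },
            fh,
            indent=2,
        )
    written.append(p)

    p = out / "tlx.csv"
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "episode": r.episode,
                "group": r.group,
                **{f"s{i + 1}": v for i, v in enumerate(r.subscales)},
                "mean_score": r.mean_score,
            }
            for r in cohort.tlx
        ]
    ).to_csv(p, index=False, float_format=FLOAT_FMT)
    written.append(p)

    p = out / "ground_truth.json"
    with open(p, "w") as fh:
        json.dump(cohort.truth.to_dict(orient="records"), fh, indent=2)
    written.append(p)

    C = cohort.layout.n_channels
    ch = cohort.layout.ids
    for rec in cohort.recordings:
        T = rec.od.shape[0]
        t = np.arange(T) / cohort.schedule.fs
        df = pd.DataFrame(
            {
                "time_s": np.repeat(t, C * 2),
                "channel_id": np.tile(np.repeat(ch, 2), T),
                "wavelength_nm": np.tile(np.array(WAVELENGTHS), T * C),
                "delta_od": rec.od.reshape(-1),
            }
        )
        p = out / f"od_{rec.subject_id}.csv"
        df.to_csv(p, index=False, float_format=FLOAT_FMT)
        written.append(p)

        mdf = pd.DataFrame(
            rec.motion,
            columns=["acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z"],
        )
        mdf.insert(0, "time_s", t)
        p = out / f"motion_{rec.subject_id}.csv"
        mdf.to_csv(p, index=False, float_format=FLOAT_FMT)
        written.append(p)
    return written


def read_cohort(in_dir: str | Path) -> Cohort:
    src = Path(in_dir)
    layout_path = src / "layout.csv"
    if not layout_path.exists():
        raise SchemaError(f"missing layout.csv in {src}")
    layout = ChannelLayout.from_frame(pd.read_csv(layout_path))

    sched_path = src / "schedule.json"
    if not sched_path.exists():
        raise SchemaError(f"missing schedule.json in {src}")
    with open(sched_path) as fh:
        sd = json.load(fh)
    schedule = ProtocolSchedule(
        tuple(Episode(e["name"], e["start_s"], e["end_s"]) for e in sd["episodes"]),
        fs=sd["fs"],
    )

    tlx_path = src / "tlx.csv"
    if not tlx_path.exists():
        raise SchemaError(f"missing tlx.csv in {src}")
    tdf = pd.read_csv(tlx_path)
    tlx = [
        TLXRecord(
            subject_id=str(r.subject_id),
            episode=str(r.episode),
            subscales=tuple(getattr(r, f"s{i + 1}") for i in range(6)),
            group=str(r.group),
        )
        for r in tdf.itertuples()
    ]

    gt_path = src / "ground_truth.json"
    truth = (
        pd.DataFrame(json.load(open(gt_path))) if gt_path.exists() else pd.DataFrame()
    )

    C = layout.n_channels
    known = set(layout.ids.tolist())
    recordings = []
    for p in sorted(src.glob("od_*.csv")):
        sid = p.stem[len("od_"):]
        df = pd.read_csv(p)
        ids = set(df["channel_id"].unique().tolist())
        extra = ids - known
        if extra:
            raise SchemaError(
                f"{p.name}: unknown channel_id {sorted(extra)[0]} not in layout"
            )
        if ids != known:
            raise SchemaError(f"{p.name}: channel set does not match layout")
        if len(df) % (C * 2) != 0:
            raise SchemaError(f"{p.name}: row count is not a multiple of C * 2")
        T = len(df) // (C * 2)
        od = df["delta_od"].to_numpy().reshape(T, C, 2)
        mp = src / f"motion_{sid}.csv"
        if not mp.exists():
            raise SchemaError(f"missing motion_{sid}.csv")
        motion = pd.read_csv(mp).drop(columns=["time_s"]).to_numpy()
        recordings.append(RawRecording(sid, layout, od, motion, schedule))
    if not recordings:
        raise SchemaError(f"no od_<id>.csv recordings found in {src}")
    return Cohort(layout, schedule, recordings, tlx, truth)


# ---------------------------------------------------------------------------
# feature matrix / stats round trip
# ---------------------------------------------------------------------------

def write_feature_matrix(matrix: ActivationMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)


def read_feature_matrix(path: str | Path, layout: ChannelLayout) -> ActivationMatrix:
    df = pd.read_csv(path)
    col_meta = pd.DataFrame(
        {
            "channel_id": layout.ids,
            "separation_cm": layout.separations,
            "hemisphere": layout.hemispheres,
            "region": layout.regions,
        }
    )
    return ActivationMatrix.from_frames(df, col_meta)


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce a full study run."""

    study: StudyConfig = field(default_factory=StudyConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    use_ssr: bool = False
    statistic: str = "sd"
    class_cm: float = 3.0
    episode: str = "task1"
    seed: int = 0
    write_recordings: bool = True

    def to_dict(self) -> dict:
        d = {
            "study": _asdict(self.study),
            "preprocess": _asdict(self.preprocess),
            "stats": _asdict(self.stats),
            "classifier": _asdict(self.classifier),
            "use_ssr": self.use_ssr,
            "statistic": self.statistic,
            "class_cm": self.class_cm,
            "episode": self.episode,
            "seed": self.seed,
            "write_recordings": self.write_recordings,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        study_d = dict(d.get("study", {}))
        physio = PhysioConfig(**_floatkeys(study_d.pop("physio", {}),
                                           ("mixing_cerebral", "mixing_superficial")))
        tlx = TLXLink(**study_d.pop("tlx", {}))
        layout_d = study_d.pop("layout", {})
        if "class_counts" in layout_d:
            layout_d["class_counts"] = {
                float(k): int(v) for k, v in layout_d["class_counts"].items()
            }
        layout = LayoutConfig(**layout_d)
        study_d = _tuplify(study_d)
        study = StudyConfig(**study_d, physio=physio, tlx=tlx, layout=layout)

        pre_d = dict(d.get("preprocess", {}))
        if "dpf" in pre_d:
            pre_d["dpf"] = {float(k): float(v) for k, v in pre_d["dpf"].items()}
        if "extinction" in pre_d:
            pre_d["extinction"] = np.asarray(pre_d["extinction"], dtype=float)
        if "band_hz" in pre_d:
            pre_d["band_hz"] = tuple(pre_d["band_hz"])
        preprocess = PreprocessConfig(**pre_d)

        return cls(
            study=study,
            preprocess=preprocess,
            stats=StatsConfig(**d.get("stats", {})),
            classifier=ClassifierConfig(**d.get("classifier", {})),
            use_ssr=bool(d.get("use_ssr", False)),
            statistic=d.get("statistic", "sd"),
            class_cm=float(d.get("class_cm", 3.0)),
            episode=d.get("episode", "task1"),
            seed=int(d.get("seed", 0)),
            write_recordings=bool(d.get("write_recordings", True)),
        )


def _plain(v):
    if isinstance(v, np.generic):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, dict):
        return {_plain(k): _plain(x) for k, x in v.items()}
    if isinstance(v, (tuple, list)):
        return [_plain(x) for x in v]
    return v


def _asdict(obj) -> dict:
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        out[f.name] = _asdict(v) if dataclasses.is_dataclass(v) else _plain(v)
    return out


def _floatkeys(d: dict, keys) -> dict:
    d = dict(d)
    for k in keys:
        if k in d:
            d[k] = {float(a): float(b) for a, b in d[k].items()}
    for k, v in d.items():
        if isinstance(v, list):
            d[k] = tuple(v)
    return d


def _tuplify(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
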