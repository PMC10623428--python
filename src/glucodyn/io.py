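"""Tidy CSV schemas, configuration, and run manifests.

Files store time in minutes (as measured at the bench); everything
internal runs in hours, and the conversion happens here and only here.
Every reader validates the header and reports malformed rows with their
line numbers; unit mismatches are errors, never silent conversions.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .cohort import Cohort
from .dynamics import ToleranceTestSeries
from .ims import PeakSpectrum

__all__ = [
    "SCHEMAS",
    "read_tolerance_csv", "write_tolerance_csv",
    "read_feeding_csv", "write_feeding_csv",
    "read_hormone_csv", "write_hormone_csv",
    "read_adipocyte_csv", "write_adipocyte_csv",
    "read_peaklist_csv", "write_peaklist_csv",
    "write_cohort", "RunManifest", "load_config",
]

SCHEMAS = {
    "tolerance": ["animal_id", "group", "sex", "week", "test_kind",
                  "time_min", "glucose_mgdl"],
    "feeding": ["group", "week", "food_g", "group_mass_g", "diet"],
    "hormone": ["animal_id", "group", "sex", "fasting_glucose_mgdl",
                "insulin_ng_ml", "leptin_ng_ml"],
    "adipocyte": ["animal_id", "group", "sex", "area_um2"],
    "peaklist": ["sample_id", "group", "bio_replicate", "tech_replicate",
                 "mz", "intensity"],
}


def _check_header(df: pd.DataFrame, schema: str, path) -> None:
    required = SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; "
                         f"expected header {required}")
    # unit discipline: the schema names carry the units; a time column
    # in hours must not masquerade as minutes
    for col in df.columns:
        if col in ("time_h", "times_h", "glucose_mmol"):
            raise ValueError(f"{path}: column {col!r} uses unsupported units; "
                             f"files store time_min and glucose_mgdl")


def _reject_bad_rows(df: pd.DataFrame, numeric_cols, path) -> pd.DataFrame:
    for col in numeric_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            # +2: header line and 1-based numbering
            lines = ", ".join(str(i + 2) for i in bad[:10])
            raise ValueError(f"{path}: malformed or missing {col!r} at line(s) {lines}")
        df[col] = vals
    return df


def read_tolerance_csv(path) -> list[ToleranceTestSeries]:
    """Read tolerance-test series; converts minutes to hours on ingestion."""
    df = pd.read_csv(path)
    _check_header(df, "tolerance", path)
    df = _reject_bad_rows(df, ["week", "time_min", "glucose_mgdl"], path)
    out = []
    for (aid, kind, week), sub in df.groupby(["animal_id", "test_kind", "week"],
                                             sort=True):
        sub = sub.sort_values("time_min")
        out.append(ToleranceTestSeries(
            subject_id=str(aid), test_kind=str(kind), week=int(week),
            times_h=sub["time_min"].to_numpy(dtype=float) / 60.0,
            glucose_mgdl=sub["glucose_mgdl"].to_numpy(dtype=float)))
    return out


def write_tolerance_csv(series_list, meta: pd.DataFrame | None, path) -> None:
    """Write series to the minute-based tidy schema.

    ``meta`` maps animal_id to group and sex (columns animal_id, group,
    sex); when absent, group and sex are left empty.
    """
    lookup = {}
    if meta is not None:
        lookup = meta.set_index("animal_id")[["group", "sex"]].to_dict("index")
    rows = []
    for s in series_list:
        gs = lookup.get(s.subject_id, {"group": "", "sex": ""})
        for t, g in zip(s.times_h, s.glucose_mgdl):
            rows.append({"animal_id": s.subject_id, "group": gs["group"],
                         "sex": gs["sex"], "week": s.week, "test_kind": s.test_kind,
                         "time_min": round(t * 60.0, 9), "glucose_mgdl": g})
    pd.DataFrame(rows, columns=SCHEMAS["tolerance"]).to_csv(path, index=False)


def read_feeding_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_header(df, "feeding", path)
    return _reject_bad_rows(df, ["week", "food_g", "group_mass_g"], path)


def write_feeding_csv(df: pd.DataFrame, path) -> None:
    df[[c for c in df.columns if c in set(SCHEMAS["feeding"]) | {"intervention", "sex"}]
       ].to_csv(path, index=False)


def read_hormone_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_header(df, "hormone", path)
    return _reject_bad_rows(df, ["fasting_glucose_mgdl", "insulin_ng_ml"], path)


def write_hormone_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_adipocyte_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_header(df, "adipocyte", path)
    return _reject_bad_rows(df, ["area_um2"], path)


def write_adipocyte_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_peaklist_csv(path) -> list[PeakSpectrum]:
    df = pd.read_csv(path)
    _check_header(df, "peaklist", path)
    df = _reject_bad_rows(df, ["mz", "intensity"], path)
    out = []
    for sid, sub in df.groupby("sample_id", sort=True):
        sub = sub.sort_values("mz")
        out.append(PeakSpectrum(
            sample_id=str(sid), group=str(sub["group"].iloc[0]),
            mz=sub["mz"].to_numpy(dtype=float),
            intensity=sub["intensity"].to_numpy(dtype=float),
            bio_replicate=str(sub["bio_replicate"].iloc[0]),
            tech_replicate=str(sub["tech_replicate"].iloc[0])))
    return out


def write_peaklist_csv(spectra, path) -> None:
    rows = []
    for s in spectra:
        for mz, it in zip(s.mz, s.intensity):
            rows.append({"sample_id": s.sample_id, "group": s.group,
                         "bio_replicate": s.bio_replicate,
                         "tech_replicate": s.tech_replicate,
                         "mz": mz, "intensity": it})
    pd.DataFrame(rows, columns=SCHEMAS["peaklist"]).to_csv(path, index=False)


def write_cohort(cohort: Cohort, outdir) -> dict[str, Path]:
    """Write every cohort table to ``outdir``; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "tolerance": outdir / "tolerance_tests.csv",
        "feeding": outdir / "feeding.csv",
        "hormone": outdir / "hormones.csv",
        "adipocyte": outdir / "adipocytes.csv",
        "peaklist": outdir / "peaklists.csv",
        "animals": outdir / "animals.csv",
        "body_mass": outdir / "body_mass.csv",
    }
    meta = cohort.animals[["animal_id", "group", "sex"]]
    write_tolerance_csv(cohort.tolerance_tests, meta, files["tolerance"])
    write_feeding_csv(cohort.feeding, files["feeding"])
    write_hormone_csv(cohort.hormones, files["hormone"])
    write_adipocyte_csv(cohort.adipocytes, files["adipocyte"])
    write_peaklist_csv(cohort.spectra, files["peaklist"])
    cohort.animals.to_csv(files["animals"], index=False)
    cohort.body_mass.to_csv(files["body_mass"], index=False)
    return files


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record written next to every pipeline output."""

    stage: str
    seed: int | None
    config: dict
    inputs: dict[str, str]
    outputs: dict[str, str]
    package_version: str = ""
    timestamp: str = ""

    @classmethod
    def create(cls, stage, seed, config, input_paths, output_paths) -> "RunManifest":
        from . import __version__

        return cls(
            stage=stage, seed=seed, config=config,
            inputs={str(p): _sha256(Path(p)) for p in input_paths},
            outputs={str(p): _sha256(Path(p)) for p in output_paths},
            package_version=__version__,
            timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        )

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()

    def write(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["config_hash"] = self.config_hash
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, default=str)


def load_config(path) -> dict:
    """Load a YAML pipeline configuration (commented template in examples/)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
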