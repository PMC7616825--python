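"""Readers, writers and run configuration.

File formats are deliberately plain: long-format CSV for the sparse
exposure records, one-dosage-column-per-variant CSV (or VCF) for the
genotypes, a two-column CSV for the outcome, JSON for fitted models and
diagnostics, YAML for run configuration.  Every writer registers its
output in a ``provenance.json`` sidecar carrying the configuration hash
and master seed of the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grids import TimeGrid
from .fpca import FpcaModel, SparseLongitudinal

logger = logging.getLogger("mpcmr")

__all__ = [
    "RunConfig",
    "read_exposure",
    "read_genotypes",
    "read_outcome",
    "write_exposure",
    "write_genotypes",
    "write_outcome",
    "write_fpca_model",
    "read_fpca_model",
    "Provenance",
]


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (YAML-loadable)."""

    out_dir: str = "mpcmr_out"
    exposure: str | None = None
    genotypes: str | None = None
    outcome: str | None = None
    simulate: dict | None = None  # SimConfig fields; replaces the three inputs
    t_min: float | None = None
    t_max: float | None = None
    fve: float = 0.95
    n_components: int | None = None
    grid_size: int = 101
    mean_bandwidth: float | None = None
    cov_bandwidth: float | None = None
    basis_kind: str = "polynomial"
    basis_degree: int = 1
    method: str = "cue_gmm"
    m: int = 41
    width: float = 4.0
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fve <= 1:
            raise ValueError("fve must lie in (0, 1]")
        if self.m < 2:
            raise ValueError("m must be at least 2")
        if self.method not in ("cue_gmm", "association"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.basis_kind not in ("polynomial", "eigenfunction"):
            raise ValueError(f"unknown basis kind {self.basis_kind!r}")
        if self.simulate is None:
            for name in ("exposure", "genotypes", "outcome"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"missing required input path: {name}")
                if not Path(path).exists():
                    raise FileNotFoundError(f"{name} file not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class Provenance:
    """Sidecar recording which run produced which files."""

    config_hash: str
    seed: int
    files: dict = field(default_factory=dict)

    def register(self, path: Path, stage: str) -> None:
        self.files[path.name] = {"stage": stage}

    def write(self, out_dir: Path) -> None:
        with open(out_dir / "provenance.json", "w") as fh:
            json.dump(
                {"config_hash": self.config_hash, "seed": self.seed, "files": self.files},
                fh,
                indent=2,
            )


def read_exposure(
    path: str | Path, t_min: float | None = None, t_max: float | None = None
) -> SparseLongitudinal:
    """Parse a long-format exposure CSV (subject_id, time, value).

    Rows with times outside an explicitly stated domain are dropped
    with a logged count; malformed numeric cells raise with the
    offending line numbers.  Duplicate (subject, time) rows are kept —
    repeated measures at one time are legitimate.
    """
    df = pd.read_csv(path)
    required = ["subject_id", "time", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("time", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()[:10]  # header is line 1
            raise ValueError(f"{path}: non-numeric {col!r} at lines {lines}")
        df[col] = coerced
    n_dup = int(df.duplicated(["subject_id", "time"]).sum())
    if n_dup:
        logger.info("%s: %d duplicate (subject, time) rows kept", path, n_dup)
    if t_min is not None or t_max is not None:
        lo = -np.inf if t_min is None else t_min
        hi = np.inf if t_max is None else t_max
        inside = (df["time"] >= lo) & (df["time"] <= hi)
        if not inside.all():
            logger.warning(
                "%s: dropped %d records outside [%s, %s]", path, int((~inside).sum()), lo, hi
            )
            df = df[inside]
    return SparseLongitudinal(df.reset_index(drop=True), t_min=t_min, t_max=t_max)


def _read_genotypes_vcf(path: str | Path) -> pd.DataFrame:
    """Dosage matrix from a VCF: the DS FORMAT field when present,
    otherwise the alt-allele count of the GT field."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    for variant in vcf:
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        ds = None
        try:
            ds = variant.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dosage = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gts = np.asarray(variant.genotype.array())[:, :2]
            dosage = np.where((gts < 0).any(axis=1), np.nan, (gts > 0).sum(axis=1)).astype(float)
        columns[vid] = dosage
    return pd.DataFrame(columns, index=pd.Index(samples, name="subject_id"))


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Read a genotype dosage matrix (CSV with subject_id column, or VCF).

    Missing cells are imputed to the column mean (logged); zero-variance
    variants are flagged but retained — downstream centering drops them.
    """
    path = Path(path)
    if path.suffix.lower() in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        df = _read_genotypes_vcf(path)
    else:
        df = pd.read_csv(path).set_index("subject_id")
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        logger.warning("%s: imputed %d missing dosages to column means", path, n_missing)
        df = df.fillna(df.mean())
    flat = df.to_numpy(dtype=float)
    if flat.size and (np.nanmin(flat) < 0 or np.nanmax(flat) > 2):
        raise ValueError(f"{path}: dosages outside [0, 2]")
    zero_var = df.columns[df.std() == 0].tolist()
    if zero_var:
        logger.warning("%s: zero-variance variants: %s", path, zero_var)
    return df


def read_outcome(path: str | Path) -> pd.Series:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns or "y" not in df.columns:
        raise ValueError(f"{path}: expected columns subject_id, y")
    y = pd.to_numeric(df["y"], errors="raise")
    return pd.Series(y.to_numpy(), index=df["subject_id"].to_numpy(), name="y")


def write_exposure(data: SparseLongitudinal, path: str | Path) -> None:
    data.records.to_csv(path, index=False)


def write_genotypes(dosages: np.ndarray, variant_ids, subject_ids, path: str | Path) -> None:
    df = pd.DataFrame(dosages, columns=list(variant_ids))
    df.insert(0, "subject_id", list(subject_ids))
    df.to_csv(path, index=False)


def write_outcome(y: np.ndarray, subject_ids, path: str | Path) -> None:
    pd.DataFrame({"subject_id": list(subject_ids), "y": y}).to_csv(path, index=False)


def write_fpca_model(model: FpcaModel, path: str | Path) -> None:
    payload = {
        "grid": model.grid.points.tolist(),
        "mu": model.mu.tolist(),
        "eigenfunctions": model.eigenfunctions.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
        "sigma2": model.sigma2,
        "fve": model.fve.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_fpca_model(path: str | Path, scores: pd.DataFrame | None = None) -> FpcaModel:
    with open(path) as fh:
        payload = json.load(fh)
    if scores is None:
        xi = np.zeros((0, len(payload["eigenvalues"])))
        subjects = np.array([])
    else:
        subjects = scores["subject_id"].to_numpy()
        xi = scores.drop(columns="subject_id").to_numpy(dtype=float)
    return FpcaModel(
        grid=TimeGrid(np.asarray(payload["grid"], dtype=float)),
        mu=np.asarray(payload["mu"], dtype=float),
        eigenfunctions=np.asarray(payload["eigenfunctions"], dtype=float),
        eigenvalues=np.asarray(payload["eigenvalues"], dtype=float),
        sigma2=float(payload["sigma2"]),
        scores=xi,
        fve=np.asarray(payload["fve"], dtype=float),
        subjects=subjects,
    )
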