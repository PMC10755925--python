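"""Readers and writers for the pipeline's delimited-text tables.

Long (tidy) CSV is the canonical interchange format everywhere; wide
matrices (the STC matrix, correlation matrices) are derived views.  All
files are UTF-8, comma-delimited, with a header row.  Floats are
written at fixed precision so repeated runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .germination import GerminationCourse
from .registry import TREATMENTS, TraitRegistry, default_registry

FLOAT_FORMAT = "%.10g"

TRAIT_COLUMNS = ["accession", "treatment", "trait", "replicate", "value"]
COURSE_COLUMNS = [
    "accession", "treatment", "replicate", "n_seeds", "day",
    "new_germinations", "moldy", "radicle_length_cm", "embryo_length_cm",
]


class TableValidationError(ValueError):
    """A table failed schema or registry validation."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableValidationError(f"{path}: missing required column(s) {missing}")


def read_trait_table(
    path: str | Path,
    registry: TraitRegistry | None = None,
) -> pd.DataFrame:
    """Read and validate a tidy trait-observation CSV.

    Trait names are resolved through the registry's aliases to canonical
    names; unknown traits, duplicate (accession, treatment, trait,
    replicate) keys, non-finite values and bad treatments are rejected
    with messages naming the offending rows.
    """
    registry = registry or default_registry()
    df = pd.read_csv(path, dtype={"accession": str, "treatment": str, "trait": str})
    _require_columns(df, TRAIT_COLUMNS, path)
    df = df[TRAIT_COLUMNS].copy()

    unknown = []
    canonical = []
    for name in df["trait"]:
        try:
            canonical.append(registry.canonical(name))
        except KeyError:
            unknown.append(name)
            canonical.append(name)
    if unknown:
        raise TableValidationError(
            f"{path}: unknown trait name(s): {sorted(set(unknown))}"
        )
    df["trait"] = canonical

    bad_treat = ~df["treatment"].isin(TREATMENTS)
    if bad_treat.any():
        raise TableValidationError(
            f"{path}: invalid treatment(s) at data row(s) "
            f"{(df.index[bad_treat] + 2).tolist()[:5]} (expected {TREATMENTS})"
        )
    values = pd.to_numeric(df["value"], errors="coerce")
    bad_val = ~np.isfinite(values)
    if bad_val.any():
        raise TableValidationError(
            f"{path}: non-numeric or non-finite value at data row(s) "
            f"{(df.index[bad_val] + 2).tolist()[:5]}"
        )
    df["value"] = values.astype(float)
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
    if (df["replicate"] < 1).any():
        raise TableValidationError(f"{path}: replicate numbers must be >= 1")

    dup = df.duplicated(subset=["accession", "treatment", "trait", "replicate"])
    if dup.any():
        first = df.loc[dup.idxmax(), ["accession", "treatment", "trait", "replicate"]]
        raise TableValidationError(
            f"{path}: duplicate observation key(s), first: {tuple(first)}"
        )
    return df.reset_index(drop=True)


def write_trait_table(df: pd.DataFrame, path: str | Path) -> None:
    df[TRAIT_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_course_table(path: str | Path) -> list[GerminationCourse]:
    """Read a germination-course CSV (one row per dish per day)."""
    df = pd.read_csv(path, dtype={"accession": str, "treatment": str})
    _require_columns(df, COURSE_COLUMNS, path)
    courses = []
    keys = ["accession", "treatment", "replicate"]
    for (acc, treatment, rep), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy()
        if not np.array_equal(days, np.arange(1, len(days) + 1)):
            raise TableValidationError(
                f"{path}: days for {acc}/{treatment}/rep{rep} must be 1..n without gaps"
            )
        courses.append(
            GerminationCourse(
                accession_id=str(acc),
                treatment=str(treatment),
                replicate=int(rep),
                new_germinations=grp["new_germinations"].to_numpy(dtype=int),
                n_seeds=int(grp["n_seeds"].iloc[0]),
                moldy=int(grp["moldy"].iloc[0]),
                radicle_length_cm=float(grp["radicle_length_cm"].iloc[0]),
                embryo_length_cm=float(grp["embryo_length_cm"].iloc[0]),
            )
        )
    return courses


def write_course_table(courses: list[GerminationCourse], path: str | Path) -> None:
    rows = []
    for c in sorted(courses, key=lambda c: c.key):
        for day, count in enumerate(c.new_germinations, start=1):
            rows.append(
                {
                    "accession": c.accession_id,
                    "treatment": c.treatment,
                    "replicate": c.replicate,
                    "n_seeds": c.n_seeds,
                    "day": day,
                    "new_germinations": int(count),
                    "moldy": c.moldy,
                    "radicle_length_cm": c.radicle_length_cm,
                    "embryo_length_cm": c.embryo_length_cm,
                }
            )
    pd.DataFrame(rows, columns=COURSE_COLUMNS).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "accession") -> None:
    df.to_csv(path, index=True, index_label=index_label, float_format=FLOAT_FORMAT)


def read_stc_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if not np.isfinite(df.to_numpy()).all():
        raise TableValidationError(f"{path}: STC matrix contains non-finite cells")
    return df


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_report(result, out_dir: str | Path, cfg: PipelineConfig | None = None,
                 inputs: list[str | Path] | None = None) -> dict[str, Path]:
    """Write the evaluation report bundle to ``out_dir``.

    Emits ranking.csv (accession, d_value, rank; sorted by rank),
    memberships.csv, loadings.csv, eigen.csv and manifest.json (config,
    seed, input checksums).  Returns the paths written.
    """
    cfg = cfg or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ranking": out / "ranking.csv",
        "memberships": out / "memberships.csv",
        "loadings": out / "loadings.csv",
        "eigen": out / "eigen.csv",
        "manifest": out / "manifest.json",
    }
    result.ranking_table().to_csv(paths["ranking"], index=False, float_format=FLOAT_FORMAT)
    write_matrix(result.membership, paths["memberships"])
    write_matrix(result.model.loadings, paths["loadings"], index_label="trait")
    result.model.eigen_table().to_csv(paths["eigen"], index=False, float_format=FLOAT_FORMAT)
    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "weights": {k: float(v) for k, v in result.weights.items()},
        "inputs": {str(p): sha256_of(p) for p in (inputs or [])},
    }
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
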