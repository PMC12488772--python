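"""Readers and writers for the package's tabular formats.

Everything is plain TSV: genotype matrices (individuals x markers, first
column the individual/line id), genetic maps (marker, chromosome,
position_morgan), long phenotype tables (individual, family, trait,
value) and crossing designs (family_id, recipient_id, donor_id,
n_progeny).  Map positions are Morgans internally; centimorgan input is
accepted with an explicit unit flag.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genetics import validate_map

__all__ = [
    "write_genotypes",
    "load_genotypes",
    "write_map",
    "load_map",
    "write_phenotypes",
    "load_phenotypes",
    "write_design",
    "load_design",
    "filter_monomorphic",
]


def write_genotypes(geno: pd.DataFrame, path) -> None:
    geno.to_csv(path, sep="\t", index_label=geno.index.name or "id")


def load_genotypes(path, kind: str = "progeny") -> pd.DataFrame:
    """Load a genotype matrix and validate its coding.

    ``kind='progeny'`` accepts dosages {0,1,2}; ``kind='parental'``
    accepts only the homozygous codes {0,2} and rejects heterozygous
    calls, reporting the offending line.  Ids must be unique.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicated individual ids: {dups[:5]}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or np.any(values != np.floor(values)):
        raise ValueError("genotype entries must be integers")
    allowed = {0, 2} if kind == "parental" else {0, 1, 2}
    bad = ~np.isin(values, list(allowed))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid {kind} genotype {values[i, j]!r} for {df.index[i]!r} "
            f"at marker {df.columns[j]!r} (file line {i + 2})"
        )
    return df.astype(np.int8)


def write_map(gmap: pd.DataFrame, path) -> None:
    gmap.to_csv(path, sep="\t", index=False)


def load_map(path, unit: str = "morgan") -> pd.DataFrame:
    gmap = pd.read_csv(path, sep="\t")
    if unit == "centimorgan":
        gmap = gmap.assign(position_morgan=gmap["position_morgan"] / 100.0)
    elif unit != "morgan":
        raise ValueError("unit must be 'morgan' or 'centimorgan'")
    return validate_map(gmap)


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, sep="\t", index=False)


def load_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"individual", "family", "trait", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return df


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def load_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"family_id", "recipient_id", "donor_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    pairs = df[["recipient_id", "donor_id"]].apply(tuple, axis=1)
    if pairs.duplicated().any():
        raise ValueError("duplicated recipient x donor pairs in design")
    return df


def filter_monomorphic(geno: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop markers with a single observed allele across the panel.

    Returns the filtered matrix and the number of markers removed.
    Raises if nothing would remain.
    """
    values = geno.to_numpy()
    poly = values.max(axis=0) != values.min(axis=0)
    n_removed = int((~poly).sum())
    if not poly.any():
        raise ValueError("all markers monomorphic: nothing left after filtering")
    return geno.loc[:, geno.columns[poly]], n_removed


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
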