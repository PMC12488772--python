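"""Quantitative-genetics machinery for BC1S2 bridging families.

This module implements the marker-level algebra the rest of the package is
built on:

* NOIA additive coefficients and the genotype-frequency-centred kinship
  matrix used by the GBLUP models,
* parental linkage disequilibrium ``D^p`` of an inbred line pair,
* the Haldane map function and the expected recombination frequency of a
  BC1S2 population,
* the progeny marker-covariance matrix ``Sigma`` of a prospective cross,
  assembled blockwise per chromosome.

Genotype coding conventions: fully inbred parental lines are coded 0/2
(copies of the donor-type allele); segregating progeny carry dosages
0/1/2.  Map positions are in Morgans throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KinshipResult",
    "ChromosomeBlock",
    "ProgenyCovariance",
    "genotype_frequencies",
    "noia_additive_coefficients",
    "kinship_noia",
    "haldane_c1",
    "bc1s2_recombination",
    "parental_ld",
    "progeny_covariance_matrix",
    "validate_map",
]

#: relative tolerance for internal symmetry / trace assertions
_TOL = 1e-8


def validate_map(gmap: pd.DataFrame) -> pd.DataFrame:
    """Validate a genetic map table and return it unchanged.

    Expects columns ``marker``, ``chromosome``, ``position_morgan`` with
    unique marker ids and nondecreasing positions within each chromosome
    (markers sorted by chromosome then position; ties — markers mapped
    to the same genetic position — are allowed).
    """
    required = {"marker", "chromosome", "position_morgan"}
    missing = required - set(gmap.columns)
    if missing:
        raise ValueError(f"genetic map missing columns: {sorted(missing)}")
    if gmap["marker"].duplicated().any():
        dups = gmap.loc[gmap["marker"].duplicated(), "marker"].tolist()
        raise ValueError(f"duplicated marker ids in map: {dups[:5]}")
    if (gmap["position_morgan"] < 0).any():
        raise ValueError("map positions must be nonnegative")
    for chrom, sub in gmap.groupby("chromosome", sort=False):
        pos = sub["position_morgan"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"positions not sorted on chromosome {chrom}")
    return gmap


def genotype_frequencies(dosages: np.ndarray) -> pd.DataFrame:
    """Per-marker genotype frequencies of a dosage matrix.

    ``BB``, ``Bb`` and ``bb`` correspond to dosages 0, 1 and 2 of the
    ``b`` (donor-type) allele, counted over the rows of ``dosages``.
    """
    dosages = np.asarray(dosages)
    if dosages.ndim != 2:
        raise ValueError("dosage matrix must be 2-D (individuals x markers)")
    n = dosages.shape[0]
    if n == 0:
        raise ValueError("empty dosage matrix")
    return pd.DataFrame(
        {
            "p_BB": (dosages == 0).sum(axis=0) / n,
            "p_Bb": (dosages == 1).sum(axis=0) / n,
            "p_bb": (dosages == 2).sum(axis=0) / n,
        }
    )


def noia_additive_coefficients(
    dosages: np.ndarray, frequencies: pd.DataFrame
) -> np.ndarray:
    """NOIA additive coefficients ``H_A`` for a dosage matrix.

    The coefficient of individual *i* at marker *j* depends on its genotype
    and on the genotype frequencies in the analysed subset::

        h_A = p_Bb + 2 p_bb       for BB (dosage 0)
        h_A = p_Bb + 2 p_bb - 1   for Bb (dosage 1)
        h_A = p_Bb + 2 p_bb - 2   for bb (dosage 2)

    i.e. each dosage column is centred by its subset mean.  The
    frequencies must be computed on the exact subset being analysed
    (family, or training plus validation set) — the caller supplies them.
    """
    dosages = np.asarray(dosages, dtype=float)
    p_bb = frequencies["p_Bb"].to_numpy() + 2.0 * frequencies["p_bb"].to_numpy()
    total = (
        frequencies["p_BB"].to_numpy()
        + frequencies["p_Bb"].to_numpy()
        + frequencies["p_bb"].to_numpy()
    )
    if not np.allclose(total, 1.0, atol=1e-6):
        raise ValueError("genotype frequencies must sum to 1 at every marker")
    return p_bb[None, :] - dosages


@dataclass
class KinshipResult:
    """NOIA kinship of a set of individuals.

    Attributes
    ----------
    h_a
        Centred-coefficient matrix, individuals x markers.
    k
        Kinship matrix ``K = H_A H_A' / (tr(H_A H_A')/n)``; its trace
        equals the number of individuals by construction.
    frequencies
        Per-marker genotype frequencies of the subset.
    """

    h_a: np.ndarray
    k: np.ndarray
    frequencies: pd.DataFrame

    @property
    def n(self) -> int:
        return self.k.shape[0]


def kinship_noia(dosages: np.ndarray) -> KinshipResult:
    """Genotype-frequency-centred additive kinship of a subset.

    Frequencies are computed on ``dosages`` itself, coefficients via
    :func:`noia_additive_coefficients`, and the cross-product is
    normalised so that ``trace(K) = n``.  Raises on a fully monomorphic
    subset (zero trace: no marker carries any coefficient variance).
    """
    dosages = np.asarray(dosages)
    n = dosages.shape[0]
    freqs = genotype_frequencies(dosages)
    h_a = noia_additive_coefficients(dosages, freqs)
    gram = h_a @ h_a.T
    tr = np.trace(gram)
    if tr <= 0 or not np.isfinite(tr):
        raise ValueError(
            "degenerate input: all markers monomorphic in this subset "
            "(kinship trace is zero)"
        )
    k = gram / (tr / n)
    return KinshipResult(h_a=h_a, k=k, frequencies=freqs)


def haldane_c1(d_morgan):
    """Haldane recombination fraction of a DH/F1-gamete population.

    ``c1 = (1 - exp(-2 d)) / 2`` for a genetic distance ``d`` in Morgans.
    Accepts scalars or arrays; ``d = inf`` (different chromosomes) gives
    the free-recombination limit 0.5.
    """
    d = np.asarray(d_morgan, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distances must be nonnegative")
    out = 0.5 * (1.0 - np.exp(-2.0 * d))
    return out.item() if np.isscalar(d_morgan) else out


def bc1s2_recombination(c1):
    """Expected recombination frequency accumulated in a BC1S2 population.

    Starting from the single-meiosis fraction ``c1`` between two markers,
    the backcross plus two selfing generations accumulate recombination
    opportunities; the expectation is::

        c = [2 c1 / (1 + 2 c1)] * (1 - (1 - 2 c1)^2 / 4)
            + ((1 - 2 c1) / 2)^2 / 2

    Note ``c(0) = 1/8``: even fully linked markers acquire a nonzero
    expected coefficient through this expression, which is applied as
    the design's working formula (see the package methods note on how it
    compares with a direct genotype-frequency computation).
    """
    c1_arr = np.asarray(c1, dtype=float)
    if np.any((c1_arr < 0) | (c1_arr > 0.5)):
        raise ValueError("c1 must lie in [0, 0.5]")
    one_minus = 1.0 - 2.0 * c1_arr
    out = (2.0 * c1_arr / (1.0 + 2.0 * c1_arr)) * (1.0 - 0.25 * one_minus**2) + 0.5 * (
        0.5 * one_minus
    ) ** 2
    return out.item() if np.isscalar(c1) else out


def _check_inbred(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.isin(x, (0.0, 2.0)).all():
        raise ValueError(f"{name} must be fully homozygous, coded 0/2")
    return x


def parental_ld(x_r: np.ndarray, x_d: np.ndarray) -> np.ndarray:
    """Linkage disequilibrium matrix ``D^p`` of an inbred parent pair.

    ``D^p = (x_R - x_D)(x_R - x_D)' / 16``.  Off-diagonal entries are 0
    whenever the parents share an allele at either marker, and +-0.25
    otherwise depending on linkage phase (coupling +, repulsion -).
    Diagonal entries are 0.25 at segregating markers, 0 elsewhere.
    """
    x_r = _check_inbred(x_r, "recipient genotype")
    x_d = _check_inbred(x_d, "donor genotype")
    if x_r.shape != x_d.shape:
        raise ValueError("parental genotype vectors differ in length")
    diff = x_r - x_d
    return np.outer(diff, diff) / 16.0


@dataclass
class ChromosomeBlock:
    """Per-chromosome slice of a progeny covariance computation."""

    chromosome: object
    index: np.ndarray  # positions of this chromosome's markers in the map order
    d_p: np.ndarray
    c1: np.ndarray
    c: np.ndarray
    sigma: np.ndarray


@dataclass
class ProgenyCovariance:
    """Marker covariance ``Sigma`` among BC1S2 progeny of one cross.

    ``Sigma_ij = D^p_ij (1 - 2 c_ij)(3 - 2 c_ij)`` with ``c_ij`` the
    expected BC1S2 recombination frequency.  Entries between chromosomes
    are exactly zero (``c = 0.5`` makes the first factor vanish), so the
    matrix is stored as per-chromosome dense blocks.
    """

    markers: pd.Index
    blocks: list[ChromosomeBlock] = field(default_factory=list)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def dense(self) -> np.ndarray:
        """Materialise the full (m x m) matrix, zeros across chromosomes."""
        m = self.n_markers
        out = np.zeros((m, m))
        for b in self.blocks:
            out[np.ix_(b.index, b.index)] = b.sigma
        return out

    def quadratic_form(self, beta: np.ndarray) -> float:
        """``beta' Sigma beta`` computed blockwise."""
        beta = np.asarray(beta, dtype=float)
        if beta.shape[0] != self.n_markers:
            raise ValueError(
                f"effect vector length {beta.shape[0]} does not match "
                f"{self.n_markers} markers"
            )
        total = 0.0
        for b in self.blocks:
            sub = beta[b.index]
            total += float(sub @ b.sigma @ sub)
        return total

    def quadratic_form_samples(self, betas: np.ndarray) -> np.ndarray:
        """Row-wise quadratic forms for a sample matrix (S x m)."""
        betas = np.asarray(betas, dtype=float)
        if betas.ndim != 2 or betas.shape[1] != self.n_markers:
            raise ValueError("sample matrix must be S x n_markers")
        out = np.zeros(betas.shape[0])
        for b in self.blocks:
            sub = betas[:, b.index]
            out += np.einsum("si,ij,sj->s", sub, b.sigma, sub)
        return out


def progeny_covariance_matrix(
    x_r: np.ndarray, x_d: np.ndarray, gmap: pd.DataFrame
) -> ProgenyCovariance:
    """Assemble ``Sigma`` for the BC1S2 progeny of one recipient x donor cross.

    Parameters
    ----------
    x_r, x_d
        Parental genotype vectors (0/2), aligned with the rows of ``gmap``.
    gmap
        Genetic map (``marker``, ``chromosome``, ``position_morgan``),
        sorted by chromosome then position.

    Returns
    -------
    ProgenyCovariance
        Blockwise ``Sigma`` plus the intermediate ``D^p``, ``c1`` and
        ``c`` matrices per chromosome.
    """
    gmap = validate_map(gmap)
    x_r = _check_inbred(x_r, "recipient genotype")
    x_d = _check_inbred(x_d, "donor genotype")
    m = len(gmap)
    if x_r.shape[0] != m or x_d.shape[0] != m:
        raise ValueError("parental genotypes do not match the number of mapped markers")

    diff = x_r - x_d
    blocks: list[ChromosomeBlock] = []
    positions = gmap["position_morgan"].to_numpy()
    chrom_codes = gmap["chromosome"].to_numpy()
    for chrom in pd.unique(chrom_codes):
        idx = np.flatnonzero(chrom_codes == chrom)
        pos = positions[idx]
        dist = np.abs(pos[:, None] - pos[None, :])
        c1 = haldane_c1(dist)
        c = bc1s2_recombination(c1)
        d_p = np.outer(diff[idx], diff[idx]) / 16.0
        sigma = d_p * (1.0 - 2.0 * c) * (3.0 - 2.0 * c)
        if not np.allclose(sigma, sigma.T, rtol=_TOL, atol=1e-12):
            raise AssertionError("Sigma block lost symmetry")
        blocks.append(
            ChromosomeBlock(
                chromosome=chrom, index=idx, d_p=d_p, c1=c1, c=c, sigma=sigma
            )
        )
    return ProgenyCovariance(markers=pd.Index(gmap["marker"]), blocks=blocks)
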