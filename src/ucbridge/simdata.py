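"""Synthetic bridging-population generator.

Emulates the data a multiparental maize pre-breeding experiment produces:
a genetic map, fully inbred elite recipient and diversity donor lines, an
incomplete recipient x donor crossing design, BC1S2 families developed by
one backcross and two generations of single-seed-descent selfing, and
additive testcross phenotypes recorded as one adjusted mean per individual.

Meiosis follows the Haldane model: crossover counts are Poisson with mean
equal to the chromosome length in Morgans and crossover positions are
uniform, i.e. no interference.  Because crossovers form a Poisson process,
transmission along a chromosome is Markov over ordered marker loci, and
the batch simulator exploits this: it draws the inherited phase marker by
marker with adjacent-interval switch probabilities given by the Haldane
map function.  Both routes produce identically distributed gametes at the
marker loci.

The default design mirrors a realistic cooperative experiment: 7
recipients, 9 donors, 20 connected families of 38-66 BC1S2 individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import haldane_c1, validate_map

__all__ = [
    "TraitArchitecture",
    "SyntheticStudy",
    "simulate_genetic_map",
    "simulate_parents",
    "simulate_design",
    "simulate_gamete",
    "simulate_gametes",
    "simulate_bc1s2_family",
    "sample_trait_architecture",
    "simulate_trait",
    "empirical_progeny_variance",
    "simulate_study",
]


# ---------------------------------------------------------------------------
# map and parents


def simulate_genetic_map(
    n_chromosomes: int,
    length_morgan: float | list[float],
    markers_per_chromosome: int | list[int],
    seed=None,
    spacing: str = "even",
) -> pd.DataFrame:
    """Generate a genetic map with even or uniformly random marker spacing.

    Returns a DataFrame (``marker``, ``chromosome``, ``position_morgan``)
    sorted by chromosome then position.  With ``spacing='even'`` markers
    run from 0 to the chromosome length inclusive; with ``'uniform'``
    positions are drawn uniformly at random and sorted.
    """
    rng = np.random.default_rng(seed)
    lengths = np.broadcast_to(np.asarray(length_morgan, dtype=float), (n_chromosomes,))
    counts = np.broadcast_to(np.asarray(markers_per_chromosome, dtype=int), (n_chromosomes,))
    if np.any(lengths <= 0):
        raise ValueError("chromosome lengths must be positive")
    if np.any(counts < 2):
        raise ValueError("need at least 2 markers per chromosome")
    rows = []
    for c in range(n_chromosomes):
        if spacing == "even":
            pos = np.linspace(0.0, lengths[c], counts[c])
        elif spacing == "uniform":
            # resample until strictly increasing (ties have measure ~0)
            pos = np.sort(rng.uniform(0.0, lengths[c], counts[c]))
            while np.any(np.diff(pos) <= 0):
                pos = np.sort(rng.uniform(0.0, lengths[c], counts[c]))
        else:
            raise ValueError(f"unknown spacing model: {spacing!r}")
        chrom = f"chr{c + 1}"
        for j, p in enumerate(pos):
            rows.append((f"{chrom}_m{j + 1}", chrom, p))
    gmap = pd.DataFrame(rows, columns=["marker", "chromosome", "position_morgan"])
    return validate_map(gmap)


def simulate_parents(
    gmap: pd.DataFrame,
    n_recipients: int,
    n_donors: int,
    seed=None,
    recipient_allele_freq: float = 0.15,
    donor_allele_freq: float = 0.5,
    freq_concentration: float = 8.0,
) -> pd.DataFrame:
    """Draw fully homozygous recipient and donor lines, coded 0/2.

    Allele-sharing model: each marker gets pool-specific frequencies of
    the donor-type allele (coded 2), drawn from Beta distributions centred
    on ``recipient_allele_freq`` and ``donor_allele_freq`` with the given
    concentration; every line then carries allele 2 independently at that
    marker with its pool's frequency.  The low recipient frequency makes
    elite lines more similar to one another than to donors, while keeping
    most recipient x donor pairs polymorphic at many markers.

    Returns a DataFrame indexed by line id (``R1..`` then ``D1..``) with
    one column per marker.
    """
    rng = np.random.default_rng(seed)
    if not 0.0 <= recipient_allele_freq <= 1.0 or not 0.0 <= donor_allele_freq <= 1.0:
        raise ValueError("allele frequencies must lie in [0, 1]")
    m = len(gmap)

    def _pool(mean, n_lines):
        if mean in (0.0, 1.0):  # degenerate pools are allowed (forced alleles)
            p = np.full(m, mean)
        else:
            a = mean * freq_concentration
            b = (1.0 - mean) * freq_concentration
            p = rng.beta(a, b, size=m)
        return (rng.random((n_lines, m)) < p[None, :]).astype(np.int8) * 2

    geno = np.vstack(
        [_pool(recipient_allele_freq, n_recipients), _pool(donor_allele_freq, n_donors)]
    )
    ids = [f"R{i + 1}" for i in range(n_recipients)] + [
        f"D{i + 1}" for i in range(n_donors)
    ]
    return pd.DataFrame(geno, index=pd.Index(ids, name="line"), columns=gmap["marker"])


def simulate_design(
    n_recipients: int = 7,
    n_donors: int = 9,
    n_families: int = 20,
    family_size_range: tuple[int, int] = (38, 66),
    seed=None,
) -> pd.DataFrame:
    """Draw an incomplete, connected recipient x donor crossing design.

    Families are allocated round-robin: recipients receive 2-3 crosses
    each and donors are cycled (shuffled) so that every donor serves
    several recipients, connecting the families through shared parents.
    Pairs are unique; family sizes are uniform over the given range.

    Returns a DataFrame (``family_id``, ``recipient_id``, ``donor_id``,
    ``n_progeny``).
    """
    if n_families < max(n_recipients, n_donors):
        raise ValueError("need at least one family per recipient and per donor")
    rng = np.random.default_rng(seed)
    recipients = [f"R{i + 1}" for i in range(n_recipients)]
    donors = [f"D{i + 1}" for i in range(n_donors)]

    # recipients cycled so per-recipient counts differ by at most one
    rec_seq = [recipients[i % n_recipients] for i in range(n_families)]
    # donors: repeated shuffled cycles, skipping duplicate pairs
    pairs: list[tuple[str, str]] = []
    used = set()
    donor_pool: list[str] = []
    for rec in rec_seq:
        while True:
            if not donor_pool:
                donor_pool = list(donors)
                rng.shuffle(donor_pool)
            don = donor_pool.pop()
            if (rec, don) not in used:
                used.add((rec, don))
                pairs.append((rec, don))
                break
    sizes = rng.integers(family_size_range[0], family_size_range[1] + 1, n_families)
    rows = [
        (f"{rec}x{don}", rec, don, int(s)) for (rec, don), s in zip(pairs, sizes)
    ]
    return pd.DataFrame(
        rows, columns=["family_id", "recipient_id", "donor_id", "n_progeny"]
    )


# ---------------------------------------------------------------------------
# meiosis


def _chrom_slices(gmap: pd.DataFrame) -> list[np.ndarray]:
    chrom = gmap["chromosome"].to_numpy()
    return [np.flatnonzero(chrom == c) for c in pd.unique(chrom)]


def simulate_gamete(haplotypes: np.ndarray, gmap: pd.DataFrame, rng) -> np.ndarray:
    """Simulate one gamete from a phased diploid by Poisson crossovers.

    ``haplotypes`` is a (2, m) array of allele indicators aligned with
    ``gmap``.  Per chromosome the crossover count is Poisson(length in
    Morgans), crossover positions are uniform along the chromosome, and
    the starting strand is random — the Haldane model without
    interference.
    """
    h = np.asarray(haplotypes)
    if h.ndim != 2 or h.shape[0] != 2:
        raise ValueError("haplotypes must be a (2, m) array")
    validate_map(gmap)
    positions = gmap["position_morgan"].to_numpy()
    gamete = np.empty(h.shape[1], dtype=h.dtype)
    for idx in _chrom_slices(gmap):
        pos = positions[idx]
        length = pos[-1] - pos[0]
        n_xo = rng.poisson(length)
        xo = np.sort(rng.uniform(pos[0], pos[-1], n_xo))
        # phase at a marker = start strand flipped once per upstream crossover
        phase = (rng.integers(0, 2) + np.searchsorted(xo, pos, side="left")) % 2
        gamete[idx] = np.where(phase == 0, h[0, idx], h[1, idx])
    return gamete


def simulate_gametes(
    h1: np.ndarray, h2: np.ndarray, gmap: pd.DataFrame, rng
) -> np.ndarray:
    """Simulate one gamete per row of paired haplotype matrices.

    ``h1`` and ``h2`` are (n, m) arrays: row i holds the two phased
    haplotypes of individual i.  Uses the Markov marker-skeleton
    equivalent of the Poisson crossover process: the inherited strand
    starts at random and switches between adjacent markers with
    probability equal to the Haldane recombination fraction of the
    interval, which yields the exact joint gamete distribution at the
    marker loci under no interference.
    """
    h1 = np.asarray(h1)
    h2 = np.asarray(h2)
    if h1.shape != h2.shape:
        raise ValueError("haplotype matrices must have equal shape")
    n, m = h1.shape
    positions = gmap["position_morgan"].to_numpy()
    phase = np.empty((n, m), dtype=bool)
    for idx in _chrom_slices(gmap):
        r_adj = haldane_c1(np.diff(positions[idx]))
        block = np.empty((n, len(idx)), dtype=bool)
        block[:, 0] = rng.random(n) < 0.5
        if len(idx) > 1:
            switches = rng.random((n, len(idx) - 1)) < r_adj[None, :]
            # cumulative XOR of switches along the chromosome
            block[:, 1:] = np.logical_xor(
                block[:, [0]], np.cumsum(switches, axis=1) % 2 == 1
            )
        phase[:, idx] = block
    return np.where(phase, h2, h1)


def simulate_bc1s2_family(
    x_r: np.ndarray,
    x_d: np.ndarray,
    gmap: pd.DataFrame,
    n_progeny: int,
    rng=None,
) -> np.ndarray:
    """Simulate BC1S2 dosages for one recipient x donor cross.

    Pipeline: F1 = R x D; each BC1 individual receives one F1 gamete and
    one recipient gamete; two generations of selfing by single-seed
    descent (one offspring advanced per plant per generation).  Returns
    an (n_progeny, m) int8 matrix of donor-allele dosages.
    """
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    rng = np.random.default_rng(rng)
    x_r = np.asarray(x_r)
    x_d = np.asarray(x_d)
    if not (np.isin(x_r, (0, 2)).all() and np.isin(x_d, (0, 2)).all()):
        raise ValueError("parents must be fully homozygous, coded 0/2")
    hr = (x_r // 2).astype(np.int8)
    hd = (x_d // 2).astype(np.int8)
    n, m = n_progeny, len(hr)

    # BC1: F1 gamete + recipient gamete (recipient is homozygous)
    f1_h1 = np.broadcast_to(hr, (n, m))
    f1_h2 = np.broadcast_to(hd, (n, m))
    bc1_a = simulate_gametes(f1_h1, f1_h2, gmap, rng)
    bc1_b = np.tile(hr, (n, 1))
    # S1 and S2: self each plant, advancing a single offspring
    a, b = bc1_a, bc1_b
    for _ in range(2):
        new_a = simulate_gametes(a, b, gmap, rng)
        new_b = simulate_gametes(a, b, gmap, rng)
        a, b = new_a, new_b
    return (a + b).astype(np.int8)


# ---------------------------------------------------------------------------
# traits


@dataclass
class TraitArchitecture:
    """Simulation-truth additive architecture of one trait.

    ``true_effects`` holds one additive effect per marker (donor-allele
    dosage scale); ``heritability`` is the individual-level h2 targeted
    when phenotypes are drawn; ``error_variance`` is resolved against the
    realised genetic variance at simulation time when left None.
    """

    name: str
    true_effects: np.ndarray
    heritability: float
    error_variance: float | None = None

    def __post_init__(self):
        if not 0.0 < self.heritability <= 1.0:
            raise ValueError("heritability must lie in (0, 1]")
        if self.error_variance is not None and self.error_variance < 0:
            raise ValueError("error variance must be nonnegative")


def sample_trait_architecture(
    n_markers: int,
    name: str = "trait",
    heritability: float = 0.5,
    effect_sd: float = 0.1,
    prop_qtl: float = 1.0,
    seed=None,
) -> TraitArchitecture:
    """Draw a Gaussian polygenic architecture.

    A fraction ``prop_qtl`` of markers receive i.i.d. N(0, effect_sd^2)
    effects; the rest are exactly zero.
    """
    rng = np.random.default_rng(seed)
    effects = np.zeros(n_markers)
    n_qtl = max(1, int(round(prop_qtl * n_markers)))
    qtl = rng.choice(n_markers, size=n_qtl, replace=False)
    effects[qtl] = rng.normal(0.0, effect_sd, n_qtl)
    return TraitArchitecture(name=name, true_effects=effects, heritability=heritability)


def simulate_trait(
    dosages: np.ndarray,
    architecture: TraitArchitecture,
    rng=None,
    intercept: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Draw one adjusted-mean phenotype per individual.

    ``phenotype = intercept + dosage @ true_effects + N(0, error_variance)``.
    If the architecture does not fix an error variance it is resolved so
    that ``h2 = var(genetic) / (var(genetic) + error_variance)`` on the
    realised genetic values.  Returns the phenotype vector and the error
    variance actually used.
    """
    rng = np.random.default_rng(rng)
    g = np.asarray(dosages, dtype=float) @ architecture.true_effects
    if architecture.error_variance is not None:
        ve = architecture.error_variance
    else:
        vg = float(np.var(g))
        ve = vg * (1.0 - architecture.heritability) / architecture.heritability
    y = intercept + g + rng.normal(0.0, np.sqrt(ve), size=g.shape[0])
    return y, ve


def empirical_progeny_variance(
    x_r: np.ndarray,
    x_d: np.ndarray,
    gmap: pd.DataFrame,
    beta: np.ndarray,
    n_progeny: int = 10_000,
    rng=None,
) -> float:
    """Brute-force progeny variance of a cross under known marker effects.

    Simulates ``n_progeny`` BC1S2 individuals and returns the sample
    variance of ``dosage @ beta``.  Serves as the simulation oracle
    against which the analytic progeny-covariance route is compared.
    """
    if n_progeny < 2:
        raise ValueError("need at least 2 progeny for a variance")
    dos = simulate_bc1s2_family(x_r, x_d, gmap, n_progeny, rng)
    return float(np.var(dos.astype(float) @ np.asarray(beta, float), ddof=1))


# ---------------------------------------------------------------------------
# whole-study generator


@dataclass
class SyntheticStudy:
    """A complete synthetic bridging experiment.

    Attributes
    ----------
    gmap
        Genetic map table.
    parents
        Parental genotypes (lines x markers, 0/2).
    design
        Crossing design (family_id, recipient_id, donor_id, n_progeny).
    progeny
        BC1S2 dosages (individuals x markers), individual ids indexed.
    families
        Family id per progeny individual (aligned with ``progeny``).
    phenotypes
        Long table: individual, family, trait, value.
    architectures
        Simulation-truth trait architectures by trait name.
    """

    gmap: pd.DataFrame
    parents: pd.DataFrame
    design: pd.DataFrame
    progeny: pd.DataFrame
    families: pd.Series
    phenotypes: pd.DataFrame
    architectures: dict[str, TraitArchitecture] = field(default_factory=dict)

    def family_members(self, family_id: str) -> list[str]:
        return list(self.families.index[self.families == family_id])

    def trait_values(self, trait: str) -> pd.Series:
        sub = self.phenotypes[self.phenotypes["trait"] == trait]
        return pd.Series(sub["value"].to_numpy(), index=sub["individual"], name=trait)


def simulate_study(
    n_chromosomes: int = 10,
    chromosome_length: float = 1.6,
    markers_per_chromosome: int = 100,
    n_recipients: int = 7,
    n_donors: int = 9,
    n_families: int = 20,
    family_size_range: tuple[int, int] = (38, 66),
    traits: dict[str, dict] | None = None,
    hidden_qtl_fraction: float = 0.25,
    seed=None,
) -> SyntheticStudy:
    """Generate a full synthetic bridging study.

    Defaults emulate the shape of a cooperative maize introgression
    experiment: 7 elite recipients, 9 diversity donors, 20 connected
    BC1S2 families of 38-66 individuals on a 10-chromosome, 16-Morgan
    genome.  ``traits`` maps a trait name to keyword arguments of
    :func:`sample_trait_architecture` (minus ``n_markers``/``name``);
    the default is a single polygenic trait at h2 = 0.5.

    A fraction ``hidden_qtl_fraction`` of the simulated loci acts as
    causal QTL and is removed from the genotype tables the analysis
    sees: the marker panel tags the QTL through co-segregation within
    families rather than containing them, as with a real SNP array.
    Prediction across families then depends on shared parental
    haplotypes (relatedness), not on direct marker effects.  Set it to
    0.0 to make every causal locus genotyped.
    """
    rng = np.random.default_rng(seed)
    gmap = simulate_genetic_map(
        n_chromosomes,
        chromosome_length,
        markers_per_chromosome,
        seed=rng,
        spacing="uniform",
    )
    parents = simulate_parents(gmap, n_recipients, n_donors, seed=rng)
    design = simulate_design(
        n_recipients, n_donors, n_families, family_size_range, seed=rng
    )

    dosage_blocks, ids, fam_labels = [], [], []
    for row in design.itertuples(index=False):
        x_r = parents.loc[row.recipient_id].to_numpy()
        x_d = parents.loc[row.donor_id].to_numpy()
        dos = simulate_bc1s2_family(x_r, x_d, gmap, row.n_progeny, rng)
        dosage_blocks.append(dos)
        ids.extend(f"{row.family_id}_{i + 1}" for i in range(row.n_progeny))
        fam_labels.extend([row.family_id] * row.n_progeny)
    progeny = pd.DataFrame(
        np.vstack(dosage_blocks),
        index=pd.Index(ids, name="individual"),
        columns=gmap["marker"],
    )
    families = pd.Series(fam_labels, index=progeny.index, name="family_id")

    if traits is None:
        traits = {"trait1": {"heritability": 0.5, "effect_sd": 0.1}}
    if not 0.0 <= hidden_qtl_fraction < 1.0:
        raise ValueError("hidden_qtl_fraction must lie in [0, 1)")
    n_loci = len(gmap)
    n_qtl = int(round(hidden_qtl_fraction * n_loci))
    qtl_pos = np.sort(rng.choice(n_loci, size=n_qtl, replace=False))
    causal_mask = np.zeros(n_loci, dtype=bool)
    causal_mask[qtl_pos] = True

    architectures: dict[str, TraitArchitecture] = {}
    pheno_rows = []
    for name, kwargs in traits.items():
        arch = sample_trait_architecture(n_loci, name=name, seed=rng, **kwargs)
        if n_qtl:  # causal effects confined to the hidden loci
            effects = np.zeros(n_loci)
            effects[qtl_pos] = arch.true_effects[qtl_pos]
            arch.true_effects = effects
        architectures[name] = arch
        y, ve = simulate_trait(progeny.to_numpy(), arch, rng=rng)
        arch.error_variance = ve
        pheno_rows.append(
            pd.DataFrame(
                {
                    "individual": progeny.index,
                    "family": families.to_numpy(),
                    "trait": name,
                    "value": y,
                }
            )
        )
    phenotypes = pd.concat(pheno_rows, ignore_index=True)
    if n_qtl:  # drop the causal loci from every table the analysis sees
        observed = ~causal_mask
        gmap = gmap.loc[observed].reset_index(drop=True)
        parents = parents.loc[:, parents.columns[observed]]
        progeny = progeny.loc[:, progeny.columns[observed]]
        for arch in architectures.values():
            arch.true_effects = arch.true_effects[observed]
    return SyntheticStudy(
        gmap=gmap,
        parents=parents,
        design=design,
        progeny=progeny,
        families=families,
        phenotypes=phenotypes,
        architectures=architectures,
    )
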