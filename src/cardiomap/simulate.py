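"""Forward simulator of the WE70 x yw crossing designs.

Generates every input the downstream mapping stages consume: diploid genomes
of parental, F1, F2, chromosome-substitution and recombinant-inbred (RIL)
individuals; heart phenotypes under a monogenic-recessive or a two-module
epistatic architecture; pooled array hybridization intensities; and low-pass
sequencing pileups.

Alleles are parental-origin labels: ``ALLELE_Y`` (0) for the *yw* laboratory
strain and ``ALLELE_W`` (1) for the WE70 wild-derived strain. Female meioses
recombine with a Poisson crossover count per arm and uniform crossover
positions; male meioses never recombine (Drosophila male achiasmy), each
male gamete carrying one intact parental haplotype per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import CHROMOSOME_ARMS, MarkerMap, make_marker_map

ALLELE_Y = 0  # yw-derived
ALLELE_W = 1  # WE70-derived

FEMALE = "female"
MALE = "male"


# ---------------------------------------------------------------------------
# Genomes and meiosis
# ---------------------------------------------------------------------------


@dataclass
class DiploidGenome:
    """Two haplotypes of parental-origin labels per chromosome arm.

    ``haplotypes[chrom]`` has shape (2, n_markers); males carry a single X
    haplotype, shape (1, n_markers). Entries are ALLELE_Y / ALLELE_W.
    """

    sex: str
    haplotypes: dict[str, np.ndarray]

    def validate(self, marker_map: MarkerMap) -> None:
        if self.sex not in (FEMALE, MALE):
            raise ValueError(f"unknown sex {self.sex!r}")
        for chrom in marker_map.chrom_names:
            h = self.haplotypes[chrom]
            expected = 1 if (chrom == "X" and self.sex == MALE) else 2
            if h.shape != (expected, marker_map.n_markers(chrom)):
                raise ValueError(f"haplotype shape mismatch on {chrom}")

    def dosage(self, chrom: str) -> np.ndarray:
        """WE70 allele dosage per marker, scaled to [0, 2] (hemizygous X counts double)."""
        h = self.haplotypes[chrom]
        if h.shape[0] == 1:
            return 2 * h[0].astype(np.int8)
        return h.sum(axis=0, dtype=np.int8)

    def is_het(self, chrom: str) -> np.ndarray:
        h = self.haplotypes[chrom]
        if h.shape[0] == 1:
            return np.zeros(h.shape[1], dtype=bool)
        return h[0] != h[1]

    def heterozygosity(self, marker_map: MarkerMap, autosomes_only: bool = False) -> float:
        chroms = marker_map.autosomes if autosomes_only else marker_map.chrom_names
        het = np.concatenate([self.is_het(c) for c in chroms])
        return float(het.mean())


def parental_genome(marker_map: MarkerMap, allele: int, sex: str) -> DiploidGenome:
    """Fully inbred parental genome: every haplotype carries ``allele``."""
    haps = {}
    for chrom in marker_map.chrom_names:
        n = marker_map.n_markers(chrom)
        ploidy = 1 if (chrom == "X" and sex == MALE) else 2
        haps[chrom] = np.full((ploidy, n), allele, dtype=np.int8)
    return DiploidGenome(sex, haps)


def _recombine(h: np.ndarray, positions: np.ndarray, length: int, rate: float,
               rng: np.random.Generator) -> np.ndarray:
    n_co = rng.poisson(rate)
    start = int(rng.integers(2))
    if n_co == 0:
        return h[start].copy()
    cx = np.sort(rng.uniform(0, length, n_co))
    phase = (start + np.searchsorted(cx, positions)) % 2
    return np.where(phase == 0, h[0], h[1]).astype(np.int8)


def meiosis(parent: DiploidGenome, marker_map: MarkerMap,
            rng: np.random.Generator) -> dict[str, np.ndarray]:
    """One gamete. Females recombine (Poisson crossovers per arm, uniform
    positions); males pass one intact haplotype per chromosome (achiasmy).

    The returned dict always includes the X: a male gamete's X is the father's
    single X, used only when the offspring is female.
    """
    gamete: dict[str, np.ndarray] = {}
    lengths = marker_map.lengths
    for chrom in marker_map.chrom_names:
        h = parent.haplotypes[chrom]
        if parent.sex == MALE:
            gamete[chrom] = h[int(rng.integers(h.shape[0]))].copy()
        else:
            gamete[chrom] = _recombine(
                h, marker_map.positions[chrom], lengths[chrom],
                marker_map.crossover_rate, rng,
            )
    return gamete


def cross(mother: DiploidGenome, father: DiploidGenome, sex: str,
          marker_map: MarkerMap, rng: np.random.Generator) -> DiploidGenome:
    """One offspring of the stated sex. X follows sex-linked transmission:
    daughters receive the father's intact X plus a maternal recombinant X;
    sons receive the maternal recombinant X only."""
    if mother.sex != FEMALE or father.sex != MALE:
        raise ValueError("cross requires a female mother and a male father")
    egg = meiosis(mother, marker_map, rng)
    sperm = meiosis(father, marker_map, rng)
    haps: dict[str, np.ndarray] = {}
    for chrom in marker_map.chrom_names:
        if chrom == "X":
            if sex == FEMALE:
                haps[chrom] = np.stack([egg[chrom], sperm[chrom]])
            else:
                haps[chrom] = egg[chrom][np.newaxis, :].copy()
        else:
            haps[chrom] = np.stack([egg[chrom], sperm[chrom]])
    return DiploidGenome(sex, haps)


# ---------------------------------------------------------------------------
# Crossing designs
# ---------------------------------------------------------------------------


def make_f1(marker_map: MarkerMap, sex: str, rng: np.random.Generator) -> DiploidGenome:
    """F1 of the mapping cross: yw males x WE70 virgin females."""
    we70_mother = parental_genome(marker_map, ALLELE_W, FEMALE)
    yw_father = parental_genome(marker_map, ALLELE_Y, MALE)
    return cross(we70_mother, yw_father, sex, marker_map, rng)


def make_f2(marker_map: MarkerMap, n: int, seed=None, sex: str = "random") -> list[DiploidGenome]:
    """F2 population from an F1 sib intercross; sexes assigned 1:1 unless forced."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    f1_mother = make_f1(marker_map, FEMALE, rng)
    f1_father = make_f1(marker_map, MALE, rng)
    out = []
    for i in range(n):
        s = sex if sex in (FEMALE, MALE) else (FEMALE if rng.integers(2) else MALE)
        out.append(cross(f1_mother, f1_father, s, marker_map, rng))
    return out


def ril_lineage(marker_map: MarkerMap, generations: int,
                rng: np.random.Generator) -> list[tuple[DiploidGenome, DiploidGenome]]:
    """Single RIL lineage: an F1 pair, then full-sib pair mating each generation.

    Returns the (female, male) sib pair of each generation; generation 1 is
    the F2. Heterozygosity decays along the classical sib-mating recursion.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    mother = make_f1(marker_map, FEMALE, rng)
    father = make_f1(marker_map, MALE, rng)
    pairs = []
    for _ in range(generations):
        daughter = cross(mother, father, FEMALE, marker_map, rng)
        son = cross(mother, father, MALE, marker_map, rng)
        pairs.append((daughter, son))
        mother, father = daughter, son
    return pairs


def make_ril_panel(marker_map: MarkerMap, n_lines: int, generations: int = 12,
                   seed=None, survival_prob: float = 1.0) -> list[DiploidGenome]:
    """Panel of RILs, one final-generation female per line.

    Each line is founded by its own F1 pair and propagated by full-sib
    mating. ``survival_prob`` < 1 models line loss during inbreeding (each
    founded line survives independently); the survivors are returned, so the
    panel may be smaller than ``n_lines``. Per-line seeds are derived
    deterministically from ``seed``.
    """
    if n_lines <= 0:
        raise ValueError("n_lines must be positive")
    if not 0.0 <= survival_prob <= 1.0:
        raise ValueError("survival_prob must lie in [0, 1]")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_lines + 1)
    loss_rng = np.random.default_rng(children[-1])
    lines = []
    for child in children[:-1]:
        rng = np.random.default_rng(child)
        if loss_rng.random() >= survival_prob and survival_prob < 1.0:
            continue
        pairs = ril_lineage(marker_map, generations, rng)
        lines.append(pairs[-1][0])
    return lines


def make_substitution_line(marker_map: MarkerMap, which: str,
                           sex: str = FEMALE) -> DiploidGenome:
    """Whole-chromosome substitution: homozygous WE70 on the named chromosome's
    arms, homozygous yw elsewhere (X is yw)."""
    key = which.removeprefix("chr")
    if key not in CHROMOSOME_ARMS or key == "X":
        raise ValueError(f"unknown substitution target {which!r}")
    arms = set(CHROMOSOME_ARMS[key])
    g = parental_genome(marker_map, ALLELE_Y, sex)
    for chrom in arms:
        g.haplotypes[chrom][:] = ALLELE_W
    return g


# ---------------------------------------------------------------------------
# Phenotype architecture
# ---------------------------------------------------------------------------


@dataclass
class ArchitectureModel:
    """Genetic architecture mapping genotype to heart phenotype.

    ``monogenic_recessive``: aberrant iff homozygous WE70 at the single causal
    locus. ``epistatic_modules``: aberrant iff every locus within at least one
    module is homozygous WE70 (conjunctive within a module, disjunctive
    between modules). With the default modules on chromosomes 2 and 3, either
    whole-chromosome substitution is aberrant, while a line carrying only part
    of a module complements the other chromosome's substitution line.

    Trait means/noises are calibrated to the strains: systolic diameter (SD)
    37 um wildtype vs 20 um aberrant with 4 um per-fly noise; arrhythmia index
    (AI) 0.06 vs 0.28 with right-skew imposed by truncation at zero. The
    diastolic diameter is SD plus a positive contraction amplitude, making DD
    and SD strongly correlated.
    """

    kind: str
    modules: list[list[tuple[str, int]]]
    sd_wildtype: float = 37.0
    sd_aberrant: float = 20.0
    sd_noise: float = 4.0
    ai_wildtype: float = 0.06
    ai_aberrant: float = 0.28
    ai_noise_wildtype: float = 0.04
    ai_noise_aberrant: float = 0.15
    dd_amplitude: float = 17.0
    dd_amplitude_noise: float = 3.0
    penetrance: float = 1.0
    affected_traits: tuple[str, ...] = ("SD", "AI")

    def __post_init__(self) -> None:
        if self.kind not in ("monogenic_recessive", "epistatic_modules"):
            raise ValueError(f"unknown architecture kind {self.kind!r}")
        if not self.modules or any(len(m) == 0 for m in self.modules):
            raise ValueError("each module must contain at least one locus")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must lie in [0, 1]")
        for noise in (self.sd_noise, self.ai_noise_wildtype,
                      self.ai_noise_aberrant, self.dd_amplitude_noise):
            if noise < 0:
                raise ValueError("noise standard deviations must be >= 0")
        if self.kind == "monogenic_recessive" and (
                len(self.modules) != 1 or len(self.modules[0]) != 1):
            raise ValueError("monogenic model takes exactly one causal locus")


def monogenic_model(locus: tuple[str, int] = ("2R", 10_000_000), **kwargs) -> ArchitectureModel:
    return ArchitectureModel("monogenic_recessive", [[locus]], **kwargs)


#: Default epistatic modules: two loci per major autosome, one per arm, so a
#: whole-chromosome substitution completes a module but a partial mosaic does not.
DEFAULT_EPISTATIC_MODULES: list[list[tuple[str, int]]] = [
    [("2L", 11_500_000), ("2R", 10_500_000)],
    [("3L", 12_200_000), ("3R", 14_000_000)],
]


def epistatic_model(modules=None, **kwargs) -> ArchitectureModel:
    if modules is None:
        modules = [list(m) for m in DEFAULT_EPISTATIC_MODULES]
    return ArchitectureModel("epistatic_modules", modules, **kwargs)


@dataclass(frozen=True)
class Phenotype:
    """Per-fly heart phenotype: systolic/diastolic diameters (um) and AI."""

    sd: float
    dd: float
    ai: float
    aberrant_sd: bool
    aberrant_ai: bool

    def __post_init__(self) -> None:
        if not (self.dd >= self.sd >= 0):
            raise ValueError("require DD >= SD >= 0")
        if self.ai < 0:
            raise ValueError("AI must be >= 0")


def is_aberrant_genotype(genome: DiploidGenome, model: ArchitectureModel,
                         marker_map: MarkerMap) -> bool:
    """Module logic on the genotype alone (no penetrance, no noise).

    A locus counts as 'homozygous WE70' when both haplotypes carry the WE70
    label (hemizygous males count their single X allele twice).
    """
    for module in model.modules:
        complete = True
        for chrom, pos in module:
            idx = marker_map.marker_index(chrom, pos)
            if genome.dosage(chrom)[idx] != 2:
                complete = False
                break
        if complete:
            return True
    return False


def assign_phenotype(genome: DiploidGenome, model: ArchitectureModel,
                     marker_map: MarkerMap, rng: np.random.Generator) -> Phenotype:
    """Draw one fly's phenotype given its genotype under ``model``.

    An aberrant-genotype fly expresses the aberrant trait means with
    probability ``penetrance``; Gaussian noise is added per fly and traits
    are truncated at zero. Traits not listed in ``affected_traits`` keep the
    wildtype distribution regardless of genotype.
    """
    aberrant = is_aberrant_genotype(genome, model, marker_map)
    expressed = aberrant and (rng.random() < model.penetrance)
    ab_sd = expressed and "SD" in model.affected_traits
    ab_ai = expressed and "AI" in model.affected_traits
    sd = rng.normal(model.sd_aberrant if ab_sd else model.sd_wildtype, model.sd_noise)
    sd = max(sd, 0.0)
    amplitude = max(rng.normal(model.dd_amplitude, model.dd_amplitude_noise), 0.0)
    ai = rng.normal(model.ai_aberrant if ab_ai else model.ai_wildtype,
                    model.ai_noise_aberrant if ab_ai else model.ai_noise_wildtype)
    return Phenotype(sd=sd, dd=sd + amplitude, ai=max(ai, 0.0),
                     aberrant_sd=ab_sd, aberrant_ai=ab_ai)


def phenotype_table(genomes: dict[str, DiploidGenome] | list[DiploidGenome],
                    model: ArchitectureModel, marker_map: MarkerMap,
                    flies_per_line: int, seed=None) -> pd.DataFrame:
    """Per-fly phenotype table for a set of lines (or individuals).

    Every fly of a line shares the line's genotype (lines are near-fixed
    stocks); phenotype noise is drawn independently per fly. Returns columns
    (line, fly, sd, dd, ai, aberrant_sd, aberrant_ai).
    """
    if not isinstance(genomes, dict):
        genomes = {str(i): g for i, g in enumerate(genomes)}
    rng = np.random.default_rng(seed)
    rows = []
    for line_id, genome in genomes.items():
        for fly in range(flies_per_line):
            p = assign_phenotype(genome, model, marker_map, rng)
            rows.append((line_id, fly, p.sd, p.dd, p.ai, p.aberrant_sd, p.aberrant_ai))
    return pd.DataFrame(rows, columns=["line", "fly", "sd", "dd", "ai",
                                       "aberrant_sd", "aberrant_ai"])


# ---------------------------------------------------------------------------
# Array intensities and sequencing pileups
# ---------------------------------------------------------------------------


def pool_allele_frequency(genomes: list[DiploidGenome], marker_map: MarkerMap) -> np.ndarray:
    """WE70 allele frequency per marker in a pool of flies (flat map order)."""
    if not genomes:
        raise ValueError("empty pool")
    total = np.zeros(marker_map.n_markers(), dtype=np.float64)
    for g in genomes:
        total += np.concatenate([g.dosage(c) for c in marker_map.chrom_names]) / 2.0
    return total / len(genomes)


def simulate_intensities(freq: np.ndarray, mu_w: np.ndarray, mu_y: np.ndarray,
                         noise_sd: float, n_replicates: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Pooled-hybridization intensities under linear mixing of parental means.

    intensity = f*mu_W + (1-f)*mu_Y + Normal(0, sd), one column per replicate
    array. Parental arrays are the f=1 and f=0 special cases.
    """
    freq = np.asarray(freq, dtype=np.float64)
    if np.any((freq < 0) | (freq > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    mean = freq * np.asarray(mu_w, float) + (1.0 - freq) * np.asarray(mu_y, float)
    noise = rng.normal(0.0, noise_sd, size=(mean.size, n_replicates)) if noise_sd > 0 \
        else np.zeros((mean.size, n_replicates))
    return mean[:, None] + noise


@dataclass
class SiteCounts:
    """Per-site read counts from a low-pass pileup (flat map order).

    ``n_error`` counts reads flipped to the other parental allele by
    sequencing error (they are already included in count_w/count_y).
    """

    sites: pd.DataFrame  # columns chrom, pos
    count_w: np.ndarray
    count_y: np.ndarray
    n_error: np.ndarray

    @property
    def depth(self) -> np.ndarray:
        return self.count_w + self.count_y


#: Fraction of sites not fixed within a re-sequenced inbred line. Low-pass
#: re-sequencing of the real RIL panel found only about two thirds of sites
#: fixed per line (incomplete inbreeding plus residual parental segregation),
#: so the re-sequencing emulation designates this fraction of sites as
#: heterozygous by default.
RIL_RESIDUAL_HET = 1.0 / 3.0

#: Mean tract length for the optional block-structured designation. Residual
#: unfixed tracts after g generations of sib mating have genetic length of
#: order 1/(2g) Morgan; at 12 generations on a 50 cM / ~22 Mb arm that is
#: ~4 cM, i.e. roughly 2 Mb.
RESIDUAL_HET_TRACT_BP = 2_000_000


def designate_het_tracts(marker_map: MarkerMap, fraction: float,
                         tract_bp: float, rng: np.random.Generator) -> np.ndarray:
    """Block-structured residual-heterozygosity mask (flat map order).

    Residual heterozygosity in an inbred line sits in contiguous
    identity-by-descent tracts, not at scattered sites. A two-state (het /
    fixed) Markov mosaic is drawn along each arm with stationary het
    probability ``fraction`` and mean het-tract length ``tract_bp``.
    """
    masks = []
    for chrom in marker_map.chrom_names:
        pos = marker_map.positions[chrom].astype(float)
        gaps = np.diff(pos, prepend=0.0)
        # switching rates of the two-state Markov chain
        out_of_het = 1.0 / tract_bp
        into_het = out_of_het * fraction / max(1.0 - fraction, 1e-12)
        state = rng.random() < fraction
        m = np.empty(pos.size, dtype=bool)
        for i, gap in enumerate(gaps):
            rate = out_of_het if state else into_het
            if rng.random() < 1.0 - np.exp(-rate * gap):
                state = not state
            m[i] = state
        masks.append(m)
    return np.concatenate(masks)


def simulate_pileups(genome: DiploidGenome, marker_map: MarkerMap,
                     coverage: float = 8.0, error_rate: float = 0.01,
                     residual_het: float | None = None,
                     het_tract_bp: float | None = None,
                     rng: np.random.Generator | None = None, seed=None) -> SiteCounts:
    """Low-pass sequencing pileup of one line.

    Depth is Poisson(``coverage``) per site. Homozygous sites emit the carried
    allele, each read flipping to the other parental allele with probability
    ``error_rate``. Heterozygous sites emit each allele with probability 0.5.
    By default the genome's genuinely heterozygous sites are used; passing
    ``residual_het`` instead designates that fraction of sites as unfixed,
    site-wise independently, or in contiguous tracts of mean length
    ``het_tract_bp`` when that is given (residual heterozygosity in real
    lines sits in identity-by-descent tracts).
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error rate must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    dosage = np.concatenate([genome.dosage(c) for c in marker_map.chrom_names])
    if residual_het is None:
        het = np.concatenate([genome.is_het(c) for c in marker_map.chrom_names])
    else:
        if not 0.0 <= residual_het <= 1.0:
            raise ValueError("residual het fraction must lie in [0, 1]")
        if het_tract_bp is None:
            het = rng.random(dosage.size) < residual_het
        else:
            het = designate_het_tracts(marker_map, residual_het, het_tract_bp, rng)
    depth = rng.poisson(coverage, size=dosage.size)
    carries_w = dosage == 2
    flips = rng.binomial(depth, error_rate)
    count_w = np.where(carries_w, depth - flips, flips)
    het_w = rng.binomial(depth, 0.5)
    count_w = np.where(het, het_w, count_w)
    n_error = np.where(het, 0, flips)
    return SiteCounts(sites=marker_map.site_table(), count_w=count_w,
                      count_y=depth - count_w, n_error=n_error)
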