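"""Forward simulation of pedigreed SNP genotypes with known ancestry.

The generator produces the study conditions every downstream stage is
tested against: several divergent gene pools (a Balding–Nichols model
around a shared ancestral allele frequency), founders drawn at
Hardy–Weinberg equilibrium within their pool, multi-generation pedigrees
built by Poisson (no-interference) meiosis on a cM map, clonal duplicates,
and a noise layer of genotype errors, missing calls and null alleles.

Every simulated haplotype is a mosaic of *founder haplotypes*; the
:class:`Truth` record keeps the mosaic (per-chromosome ancestry segments)
plus the founder allele matrix, so true IBD sharing, ancestry fractions
and transmitted gametes are all recoverable exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import HET, HOM_A, HOM_B, MISSING, GeneticMap, GenotypePanel, \
    make_metadata

# Founder-haplotype allele codes: 0 = A, 1 = B, 2 = null (assay-invisible).
NULL_ALLELE = 2

#: Truth classification labels.
LABEL_PURE = "pure"
LABEL_HYBRID = "hybrid"
LABEL_COMPONENT = "component"
LABEL_FULLY_CULTIVAR = "fully_cultivar"


@dataclass(frozen=True)
class SpeciesModel:
    """Divergent gene pools around a common ancestral frequency.

    Per SNP, an ancestral frequency is drawn Uniform(freq_low, freq_high)
    and each pool's frequency from a Beta with mean equal to the ancestral
    frequency and an FST-controlled spread (Balding–Nichols).
    """

    n_species: int
    fst: float = 0.3
    freq_low: float = 0.05
    freq_high: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie strictly in (0, 1)")
        if self.n_species < 1:
            raise ValueError("need at least one species")

    def draw_frequencies(self, n_snps: int, rng: np.random.Generator
                         ) -> np.ndarray:
        """(n_species, n_snps) allele frequencies, all strictly in (0,1)."""
        p = rng.uniform(self.freq_low, self.freq_high, size=n_snps)
        scale = (1.0 - self.fst) / self.fst
        freqs = rng.beta(p * scale, (1.0 - p) * scale,
                         size=(self.n_species, n_snps))
        return np.clip(freqs, 1e-6, 1.0 - 1e-6)


@dataclass(frozen=True)
class FounderGroup:
    name: str
    n: int
    reference_group: str = "unknown"   # cultivar / wild / exotic / unknown
    recorded_species: str | None = None

    @property
    def species_label(self) -> str:
        return self.recorded_species if self.recorded_species else self.name


@dataclass(frozen=True)
class Mating:
    id: str
    father: str
    mother: str
    reference_group: str = "unknown"
    recorded_species: str | None = None


@dataclass(frozen=True)
class Clone:
    id: str
    source: str
    reference_group: str = "unknown"
    recorded_species: str | None = None


@dataclass(frozen=True)
class PedigreeSpec:
    """Ordered matings plus clone directives; parents must precede offspring."""

    matings: tuple[Mating, ...] = ()
    clones: tuple[Clone, ...] = ()

    def validate(self, existing_ids: set[str]) -> None:
        known = set(existing_ids)
        for m in self.matings:
            if m.father not in known or m.mother not in known:
                raise ValueError(
                    f"mating {m.id!r}: parents must precede offspring "
                    f"({m.father!r} x {m.mother!r})")
            if m.id in known:
                raise ValueError(f"duplicate individual id {m.id!r}")
            known.add(m.id)
        for c in self.clones:
            if c.source not in known:
                raise ValueError(f"clone {c.id!r}: unknown source {c.source!r}")
            if c.id in known:
                raise ValueError(f"duplicate individual id {c.id!r}")
            known.add(c.id)


@dataclass(frozen=True)
class NoiseModel:
    genotype_error_rate: float = 0.002
    missing_rate: float = 0.01
    null_allele_rate: float = 0.0      # per SNP per founder haplotype

    def __post_init__(self) -> None:
        for v in (self.genotype_error_rate, self.null_allele_rate):
            if not 0.0 <= v < 1.0:
                raise ValueError("noise rates must lie in [0, 1)")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")


# A haplotype is, per chromosome, a list of (start_cM, end_cM, founder_hap_id)
# segments partitioning the SNP-covered span.
ChromSegments = list[tuple[float, float, int]]


@dataclass
class Haplotype:
    segments: list[ChromSegments]

    def copy(self) -> "Haplotype":
        return Haplotype([list(c) for c in self.segments])


@dataclass
class Truth:
    """Ground-truth record for a simulated panel."""

    gmap: GeneticMap
    founder_alleles: np.ndarray            # (n_founder_haps, n_snps) in {0,1}
    hap_species: list[str]                 # founder group name per haplotype
    hap_owner: list[str]                   # founder individual per haplotype
    cultivar_groups: set[str]              # group names counting as cultivar
    haplotypes: dict[str, tuple[Haplotype, Haplotype]] = field(default_factory=dict)
    parents: dict[str, tuple[str | None, str | None]] = field(default_factory=dict)
    clone_of: dict[str, str] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)

    # -- materialization ---------------------------------------------------
    def hap_alleles(self, iid: str, which: int,
                    alleles: np.ndarray | None = None) -> np.ndarray:
        """Allele vector (0/1, or 2 for null) carried by one haplotype."""
        src = self.founder_alleles if alleles is None else alleles
        gmap = self.gmap
        out = np.empty(gmap.n_snps, dtype=np.int8)
        hap = self.haplotypes[iid][which]
        for ci, chrom in enumerate(gmap.chromosomes):
            sl = gmap.chrom_slice(chrom)
            pos = gmap.positions[sl]
            segs = hap.segments[ci]
            cuts = np.searchsorted(pos, [s[0] for s in segs[1:]], side="left")
            prev = 0
            for (s, e, hid), nxt in zip(segs, [*cuts, len(pos)]):
                out[sl][prev:nxt] = src[hid, sl][prev:nxt]
                prev = nxt
        return out

    def genotypes(self, iid: str, alleles: np.ndarray | None = None
                  ) -> np.ndarray:
        """Displayed (assay) genotype: null alleles hide behind the other."""
        a = self.hap_alleles(iid, 0, alleles)
        b = self.hap_alleles(iid, 1, alleles)
        return _display(a, b)

    # -- truth queries -----------------------------------------------------
    def ancestry_fractions(self, iid: str) -> dict[str, float]:
        """Fraction of the (diploid) genome from each founder group."""
        totals: dict[str, float] = {}
        for hap in self.haplotypes[iid]:
            for chrom_segs in hap.segments:
                for s, e, hid in chrom_segs:
                    g = self.hap_species[hid]
                    totals[g] = totals.get(g, 0.0) + (e - s)
        denom = 2.0 * self.gmap.total_cM
        if denom == 0.0:  # zero-length map: ancestry fractions undefined
            return {}
        return {g: v / denom for g, v in totals.items()}

    def cultivar_fraction(self, iid: str) -> float:
        fr = self.ancestry_fractions(iid)
        return sum(v for g, v in fr.items() if g in self.cultivar_groups)

    def ibd_diploid_fraction(self, id_a: str, id_b: str) -> float:
        """Fraction of the diploid genome shared IBD between two individuals.

        Computed by interval sweep over founder-haplotype ancestry: at each
        map position the pair shares IBD if any of a's two founder ids
        matches any of b's.  A parent and offspring share exactly 50%; a
        grandparent and grandchild on average 25%.
        """
        shared = 0.0
        for ci in range(len(self.gmap.chromosomes)):
            lists = [h.segments[ci] for h in self.haplotypes[id_a]] + \
                    [h.segments[ci] for h in self.haplotypes[id_b]]
            cuts = sorted({x for segs in lists for s, e, _ in segs for x in (s, e)})
            for u, v in zip(cuts, cuts[1:]):
                mid = 0.5 * (u + v)
                ids_a = {_id_at(lists[0], mid), _id_at(lists[1], mid)}
                ids_b = {_id_at(lists[2], mid), _id_at(lists[3], mid)}
                if ids_a & ids_b:
                    shared += v - u
        return shared / (2.0 * self.gmap.total_cM)


def _id_at(segs: ChromSegments, x: float) -> int:
    for s, e, hid in segs:
        if s <= x <= e:
            return hid
    raise ValueError(f"position {x} outside haplotype segments")


def _display(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Assay view of two allele vectors; nulls are invisible."""
    out = (a + b).astype(np.int8)
    a_null = a == NULL_ALLELE
    b_null = b == NULL_ALLELE
    out[a_null] = np.where(b[a_null] == 0, HOM_A, HOM_B)
    out[b_null] = np.where(a[b_null] == 0, HOM_A, HOM_B)
    out[a_null & b_null] = MISSING
    return out


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

def simulate_founders(model: SpeciesModel, groups: list[FounderGroup],
                      gmap: GeneticMap, seed: int | np.random.Generator
                      ) -> tuple[GenotypePanel, Truth]:
    """Draw founder panels at Hardy–Weinberg within each gene pool.

    One gene pool per group, in order; individual ids are
    ``{group}_{index:03d}``.  Groups whose ``reference_group`` is
    ``cultivar`` define the cultivar gene pool for truth labels.
    """
    if len(groups) != model.n_species:
        raise ValueError("one FounderGroup per species expected")
    rng = np.random.default_rng(seed)
    freqs = model.draw_frequencies(gmap.n_snps, rng)
    n_chrom = len(gmap.chromosomes)

    hap_rows: list[np.ndarray] = []
    hap_species: list[str] = []
    hap_owner: list[str] = []
    haplotypes: dict[str, tuple[Haplotype, Haplotype]] = {}
    ids: list[str] = []
    species_labels: list[str] = []
    ref_groups: list[str] = []

    def founder_hap(chrom_spans: list[tuple[float, float]], hid: int) -> Haplotype:
        return Haplotype([[(s, e, hid)] for s, e in chrom_spans])

    spans = [(float(gmap.chrom_positions(c)[0]), float(gmap.chrom_positions(c)[-1]))
             for c in gmap.chromosomes]
    for gi, grp in enumerate(groups):
        if grp.n < 1:
            raise ValueError(f"group {grp.name!r} needs n >= 1")
        for k in range(grp.n):
            iid = f"{grp.name}_{k:03d}"
            hids = (len(hap_rows), len(hap_rows) + 1)
            for _ in range(2):
                hap_rows.append((rng.random(gmap.n_snps) < freqs[gi])
                                .astype(np.int8))
                hap_species.append(grp.name)
                hap_owner.append(iid)
            haplotypes[iid] = (founder_hap(spans, hids[0]),
                               founder_hap(spans, hids[1]))
            ids.append(iid)
            species_labels.append(grp.species_label)
            ref_groups.append(grp.reference_group)

    truth = Truth(gmap=gmap,
                  founder_alleles=np.array(hap_rows, dtype=np.int8),
                  hap_species=hap_species, hap_owner=hap_owner,
                  cultivar_groups={g.name for g in groups
                                   if g.reference_group == "cultivar"},
                  haplotypes=haplotypes,
                  parents={i: (None, None) for i in ids})
    calls = np.array([truth.genotypes(i) for i in ids])
    panel = GenotypePanel(gmap, make_metadata(ids, species_labels, ref_groups),
                          calls)
    for iid in ids:
        truth.labels[iid] = _label(truth, iid)
    return panel, truth


# ---------------------------------------------------------------------------
# meiosis and pedigrees
# ---------------------------------------------------------------------------

def meiosis(phased_parent: tuple[Haplotype, Haplotype], gmap: GeneticMap,
            rng: int | np.random.Generator
            ) -> tuple[Haplotype, list[list[float]]]:
    """One gamete under the no-interference (Haldane/Poisson) model.

    Per chromosome the crossover count is Poisson(span_cM / 100), positions
    are uniform on the SNP-covered span, and the starting homolog is chosen
    with probability 1/2.  Returns the gamete haplotype (with its founder
    ancestry mosaic) and the crossover positions per chromosome.
    """
    if (not isinstance(phased_parent, tuple) or len(phased_parent) != 2
            or not all(isinstance(h, Haplotype) for h in phased_parent)):
        raise TypeError("phased_parent must be a (Haplotype, Haplotype) pair")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    out_segments: list[ChromSegments] = []
    crossovers: list[list[float]] = []
    for ci, chrom in enumerate(gmap.chromosomes):
        pos = gmap.chrom_positions(chrom)
        lo, hi = float(pos[0]), float(pos[-1])
        span = hi - lo
        k = int(rng.poisson(span / 100.0)) if span > 0 else 0
        xs = sorted(float(x) for x in rng.uniform(lo, hi, size=k))
        crossovers.append(xs)
        source = int(rng.integers(2))
        segs: ChromSegments = []
        cuts = [lo, *xs, hi]
        for a, b in zip(cuts, cuts[1:]):
            segs.extend(_slice_segments(phased_parent[source].segments[ci], a, b))
            source = 1 - source
        out_segments.append(_merge_adjacent(segs))
    return Haplotype(out_segments), crossovers


def _slice_segments(segs: ChromSegments, lo: float, hi: float) -> ChromSegments:
    out: ChromSegments = []
    for s, e, hid in segs:
        a, b = max(s, lo), min(e, hi)
        if b > a or (b == a and lo == hi):
            out.append((a, b, hid))
    return out


def _merge_adjacent(segs: ChromSegments) -> ChromSegments:
    out: ChromSegments = []
    for s, e, hid in segs:
        if out and out[-1][2] == hid and out[-1][1] == s:
            out[-1] = (out[-1][0], e, hid)
        else:
            out.append((s, e, hid))
    return out


def build_pedigree(spec: PedigreeSpec, panel: GenotypePanel, truth: Truth,
                   seed: int | np.random.Generator
                   ) -> tuple[GenotypePanel, Truth]:
    """Extend a founder panel with matings and clones.

    Each non-founder is the union of one gamete from each parent; clones
    copy haplotypes (hence pre-noise genotypes) exactly.  Truth labels are
    (re)assigned for all new individuals: ``fully_cultivar`` when the whole
    founder ancestry is from cultivar groups, ``hybrid`` for one
    fully-cultivar parent or grandparent, ``component`` when cultivar
    ancestry exceeds 10% at deeper generations, else ``pure``.
    """
    spec.validate(set(panel.ids))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) \
        else seed
    truth = replace(truth,
                    haplotypes=dict(truth.haplotypes),
                    parents=dict(truth.parents),
                    clone_of=dict(truth.clone_of),
                    labels=dict(truth.labels))
    out = panel
    for m in spec.matings:
        gam_f, _ = meiosis(truth.haplotypes[m.father], truth.gmap, rng)
        gam_m, _ = meiosis(truth.haplotypes[m.mother], truth.gmap, rng)
        truth.haplotypes[m.id] = (gam_f, gam_m)
        truth.parents[m.id] = (m.father, m.mother)
        species = m.recorded_species or \
            out.metadata.loc[m.father, "recorded_species"]
        out = out.with_individual(m.id, species, m.reference_group,
                                  truth.genotypes(m.id))
    for c in spec.clones:
        truth.haplotypes[c.id] = tuple(h.copy()
                                       for h in truth.haplotypes[c.source])
        truth.parents[c.id] = truth.parents[c.source]
        truth.clone_of[c.id] = c.source
        species = c.recorded_species or \
            out.metadata.loc[c.source, "recorded_species"]
        out = out.with_individual(c.id, species, c.reference_group,
                                  out.genotypes(c.source).copy())
    for iid in [m.id for m in spec.matings] + [c.id for c in spec.clones]:
        truth.labels[iid] = _label(truth, iid)
    return out, truth


def _label(truth: Truth, iid: str) -> str:
    src = truth.clone_of.get(iid, iid)
    cf = truth.cultivar_fraction(src)
    if cf >= 1.0 - 1e-9:
        return LABEL_FULLY_CULTIVAR
    near = []
    for p in truth.parents[src]:
        if p is not None:
            near.append(p)
            near.extend(q for q in truth.parents.get(p, (None, None)) if q)
    if any(truth.cultivar_fraction(a) >= 1.0 - 1e-9 for a in near):
        return LABEL_HYBRID
    if cf > 0.10:
        return LABEL_COMPONENT
    return LABEL_PURE


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

@dataclass
class NoiseOutcome:
    panel: GenotypePanel
    null_mask: np.ndarray      # (n_founder_haps, n_snps) bool
    error_mask: np.ndarray     # (n_ind, n_snps) bool
    missing_mask: np.ndarray   # (n_ind, n_snps) bool


def apply_noise_detailed(panel: GenotypePanel, truth: Truth, noise: NoiseModel,
                         seed: int | np.random.Generator) -> NoiseOutcome:
    """Noise layer with the sampled masks exposed (for audits and tests).

    Null alleles are a third, silent founder allele: a true A-null shows as
    HOM_A and a true null-null as MISSING; being founder-level they are
    inherited, so an offspring receiving the null can display an apparent
    opposing homozygote against its own parent.  Random genotype errors
    then flip calls to a uniformly chosen other non-missing state, and
    missingness is applied last.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) \
        else seed
    null_mask = rng.random(truth.founder_alleles.shape) < noise.null_allele_rate
    if null_mask.any():
        alleles = truth.founder_alleles.copy()
        alleles[null_mask] = NULL_ALLELE
        calls = np.array([truth.genotypes(i, alleles) for i in panel.ids])
    else:
        calls = panel.calls.copy()

    error_mask = (rng.random(calls.shape) < noise.genotype_error_rate) \
        & (calls != MISSING)
    if error_mask.any():
        shift = rng.integers(1, 3, size=int(error_mask.sum()))
        calls[error_mask] = ((calls[error_mask] + shift) % 3).astype(np.int8)

    missing_mask = rng.random(calls.shape) < noise.missing_rate
    calls[missing_mask] = MISSING
    out = GenotypePanel(panel.gmap, panel.metadata, calls)
    return NoiseOutcome(out, null_mask, error_mask, missing_mask)


def apply_noise(panel: GenotypePanel, truth: Truth, noise: NoiseModel,
                seed: int | np.random.Generator) -> GenotypePanel:
    return apply_noise_detailed(panel, truth, noise, seed).panel


# ---------------------------------------------------------------------------
# convenience: cultivar panel with internal pedigree depth
# ---------------------------------------------------------------------------

def grandparent_sharing_replicates(n_replicates: int,
                                   seed: int | np.random.Generator,
                                   gmap: GeneticMap | None = None
                                   ) -> np.ndarray:
    """True grandparent-grandchild diploid IBD fractions over replicates.

    Each replicate simulates grandparent x spouse -> parent x spouse ->
    grandchild (two successive meioses) and reads the shared fraction off
    the truth record; the theoretical mean is 25%.  SNP content is
    irrelevant to the truth, so a sparse map with the same chromosome
    spans is used (two SNPs per chromosome).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) \
        else seed
    if gmap is None:
        gmap = GeneticMap.default(n_snps=34)
    model = SpeciesModel(n_species=1)
    groups = [FounderGroup("pool", 4)]
    out = np.empty(n_replicates)
    for r in range(n_replicates):
        panel, truth = simulate_founders(model, groups, gmap, rng)
        spec = PedigreeSpec(matings=(
            Mating("parent", "pool_000", "pool_001"),
            Mating("grandchild", "parent", "pool_002")))
        _, truth = build_pedigree(spec, panel, truth, rng)
        out[r] = truth.ibd_diploid_fraction("grandchild", "pool_000")
    return out


def simulate_audit_panel(seed: int | np.random.Generator,
                         gmap: GeneticMap | None = None,
                         n_cultivar_founders: int = 10,
                         n_cultivar_depth2: int = 4,
                         n_wild: int = 10, n_f1: int = 5, n_clones: int = 3,
                         noise: NoiseModel = NoiseModel()
                         ) -> tuple[GenotypePanel, Truth]:
    """A canonical genebank audit scenario with recoverable truth.

    A cultivar reference panel with second-generation depth, pure wild
    accessions, F1 cultivar x wild hybrids, and clones of depth-2
    cultivars deposited under wild species labels — the situations the
    classifier must untangle.  Noise defaults emulate array data (0.2%
    genotype error, 1% missing calls).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) \
        else seed
    gmap = gmap if gmap is not None else GeneticMap.default()
    model = SpeciesModel(n_species=2, fst=0.3)
    groups = [FounderGroup("domestica", n_cultivar_founders, "cultivar"),
              FounderGroup("sieversii", n_wild, "unknown")]
    panel, truth = simulate_founders(model, groups, gmap, rng)
    matings = list(cultivar_depth_matings(
        [f"domestica_{k:03d}" for k in range(n_cultivar_founders)],
        n_cultivar_depth2, rng, recorded_species="domestica"))
    for k in range(n_f1):
        matings.append(Mating(
            f"f1_{k:03d}", f"domestica_{k % n_cultivar_founders:03d}",
            f"sieversii_{k % n_wild:03d}", "unknown", "sieversii"))
    clones = tuple(Clone(f"clone_{k:03d}", f"cv_g2_{k % n_cultivar_depth2:03d}",
                         "unknown", "sieversii")
                   for k in range(n_clones))
    spec = PedigreeSpec(matings=tuple(matings), clones=clones)
    panel, truth = build_pedigree(spec, panel, truth, rng)
    return apply_noise(panel, truth, noise, rng), truth


def cultivar_depth_matings(founder_ids: list[str], n_offspring: int,
                           rng: np.random.Generator, prefix: str = "cv_g2",
                           reference_group: str = "cultivar",
                           recorded_species: str | None = None
                           ) -> tuple[Mating, ...]:
    """Matings giving a cultivar panel second-generation depth.

    Cultivar collections are endogamous (cultivars descend from other
    cultivars); crossing random founder pairs reproduces the inflated
    within-cultivar SPLoSH background that motivates the conservative
    relationship thresholds.
    """
    matings = []
    for k in range(n_offspring):
        f, m = rng.choice(len(founder_ids), size=2, replace=False)
        matings.append(Mating(f"{prefix}_{k:03d}", founder_ids[int(f)],
                              founder_ids[int(m)], reference_group,
                              recorded_species))
    return tuple(matings)
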