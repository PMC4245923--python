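"""Synthetic allele catalogs and hybridization signal simulation.

The generator emulates the structure that makes array-based HLA typing hard:
loci whose sequences share >85% identity (so probes can be masked across
loci), serotype families of near-identical alleles (>98% identity within a
serotype), smooth positive-signal profiles along the overlapping-probe track,
low-valued negative probes, per-array scale variation, globally attenuated
(degraded) arrays, mixed samples, and engineered full masking in the style of
the classic homozygote-vs-masked-heterozygote ambiguity.

Catalogs descend from a single ancestor sequence: per-locus roots by
cross-locus substitutions, serotype founders by between-serotype
substitutions, and sibling alleles by a handful of private substitutions —
so per-locus alignments are columnar by construction (no indels by default).

Signals: a unique probe is positive iff it occurs in at least one present
allele (shared placements included, so masking emerges naturally).  Positive
contributions follow a smooth per-sample hybridization-efficiency profile
along each allele track; all probes carry multiplicative lognormal noise and
a per-array scale factor.  The profile is a property of the *sample* (the
labeled cRNA preparation), so replicate arrays of one sample share it while
different samples do not — which is what separates replicate-pair from
distinct-sample correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .catalog import AlleleCatalog, AlleleSequence, SerogroupTable
from .errors import ConfigError, GenotypeError
from .genotyping import Genotype
from .probes import ProbeSet, build_probe_set
from .signals import ArraySignals

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for the synthetic catalogs and arrays.

    Divergences are substitution counts per derivation step; identities the
    resulting pairwise levels on the default 360 nt sequences.  Signal means
    are in raw RFU; noise/profile/scale sigmas are lognormal standard
    deviations (natural-log scale).
    """

    n_loci: int = 3
    serotypes_per_locus: int = 8
    alleles_per_serotype: int = 4
    sequence_length: int = 360
    within_serotype_divergence: int = 2
    between_serotype_divergence: int = 18
    cross_locus_identity: float = 0.88
    related_serotype_pairs: int = 0
    related_divergence: int = 4
    noise_sd: float = 0.12
    profile_sd: float = 0.2
    profile_corr: float = 15.0
    scale_sd: float = 0.4
    positive_mean: float = 4000.0
    negative_mean: float = 100.0
    degradation_factor: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.within_serotype_divergence < 1 or self.between_serotype_divergence < 1:
            raise ConfigError("divergences must be at least 1 substitution")
        if self.positive_mean <= self.negative_mean:
            raise ConfigError("positive_mean must exceed negative_mean")
        if not 0.0 <= self.cross_locus_identity <= 1.0:
            raise ConfigError("cross_locus_identity must be a fraction in [0,1]")


@dataclass
class SimulatedSample:
    sample_id: str
    truth_genotype: Genotype
    signals: ArraySignals  # raw stage
    scenario: str
    replicate_of: str | None = None


# ---------------------------------------------------------------------------
# catalog generation
# ---------------------------------------------------------------------------

def _mutate(seq: np.ndarray, n_subs: int, rng: np.random.Generator) -> np.ndarray:
    """Substitute ``n_subs`` distinct positions to a different base."""
    out = seq.copy()
    if n_subs == 0:
        return out
    pos = rng.choice(seq.size, size=min(n_subs, seq.size), replace=False)
    for p in pos:
        choices = _BASES[_BASES != out[p]]
        out[p] = rng.choice(choices)
    return out


def _to_str(seq: np.ndarray) -> str:
    return seq.tobytes().decode()


_LOCUS_NAMES = ["A", "B", "C", "D", "E", "F", "G", "H"]


def generate_allele_catalog(
    config: SimConfig,
) -> tuple[AlleleCatalog, SerogroupTable]:
    """Catalog + serogroup table with controlled similarity structure.

    Class I polymorphism within an allele group concentrates at a small set
    of hypervariable sites shared across groups, which is what gives every
    group very close allele pairs (two alleles differing by one or two
    nucleotides).  The generator mirrors that: each locus carries
    ``within_serotype_divergence`` hypervariable columns (placed away from
    the sequence ends and from each other), and the alleles of a serotype are
    the founder with a serotype-specific variant base at distinct subsets of
    those columns — so within-group distances are 1..d substitutions and are
    the same for every group, while serotype founders differ from the locus
    root at ``between_serotype_divergence`` random positions and locus roots
    descend from one ancestor (``cross_locus_identity`` controls sharing and
    hence cross-locus probe masking).  When ``related_serotype_pairs > 0``,
    the founders of serotypes (1,2), (3,4)... of each locus are related by
    only ``related_divergence`` substitutions and share a serogroup
    (emulating pairs like A*03/A*11 that cannot be separated at serotype
    level).
    """
    rng = np.random.default_rng(config.seed)
    L = config.sequence_length
    margin = 60  # keep hypervariable columns a probe length away from ends
    n_cols = config.within_serotype_divergence
    while 2**n_cols < config.alleles_per_serotype:
        n_cols += 1  # need enough column subsets for the requested alleles
    if L < 2 * margin + n_cols * margin:
        raise ConfigError("sequence_length too short for the hypervariable column layout")
    ancestor = rng.choice(_BASES, size=L)
    # per-root substitutions chosen so the *pairwise* identity between alleles
    # of different loci lands near cross_locus_identity once the
    # between-serotype and column divergence (shared by both sides) is counted
    pair_target = (1.0 - config.cross_locus_identity) * L
    cross_subs = max(
        0,
        int(round((pair_target - 2 * config.between_serotype_divergence - n_cols) / 2)),
    )
    alleles: list[AlleleSequence] = []
    groups: dict[str, str] = {}
    seen_seqs: set[str] = set()
    if config.n_loci > len(_LOCUS_NAMES):
        raise ConfigError(f"at most {len(_LOCUS_NAMES)} loci supported")
    # allele -> column subsets, smallest first (0 = founder itself)
    subsets = sorted(
        (tuple(j for j in range(n_cols) if mask >> j & 1) for mask in range(2**n_cols)),
        key=lambda s: (len(s), s),
    )[: config.alleles_per_serotype]
    for li in range(config.n_loci):
        locus = _LOCUS_NAMES[li]
        root = _mutate(ancestor, cross_subs, rng)
        # hypervariable columns: probe-length spacing, away from the ends
        columns = margin + np.sort(
            rng.choice((L - 2 * margin) // margin, size=n_cols, replace=False)
        ) * margin + rng.integers(0, margin // 2, size=n_cols)
        founders: list[np.ndarray] = []
        for si in range(config.serotypes_per_locus):
            serotype = f"{locus}*{si + 1:02d}"
            paired = (
                si % 2 == 1 and si // 2 < config.related_serotype_pairs and founders
            )
            if paired:
                founder = _mutate(founders[si - 1], config.related_divergence, rng)
                groups[serotype] = f"{locus}-g{(si - 1) // 2 + 1:02d}"
                groups[f"{locus}*{si:02d}"] = f"{locus}-g{(si - 1) // 2 + 1:02d}"
            else:
                founder = _mutate(root, config.between_serotype_divergence, rng)
            # polymorphism clusters: every group carries a distinct signature
            # right next to each hypervariable column, so probes spanning a
            # column always differ between groups (no accidental cross-group
            # identity of the variant windows)
            for c in columns:
                alts0 = _BASES[_BASES != root[c + 1]]
                alts1 = _BASES[_BASES != root[c + 2]]
                founder[c + 1] = alts0[si % 3]
                founder[c + 2] = alts1[(si // 3) % 3]
            founders.append(founder)
            variants = np.array(
                [rng.choice(_BASES[_BASES != founder[c]]) for c in columns]
            )
            for ai, subset in enumerate(subsets):
                name = f"{serotype}:{ai + 1:02d}"
                seq = founder.copy()
                for j in subset:
                    seq[columns[j]] = variants[j]
                if _to_str(seq) in seen_seqs:
                    raise ConfigError(
                        "allele sequences collide; raise the divergence settings"
                    )
                seen_seqs.add(_to_str(seq))
                alleles.append(AlleleSequence(name, _to_str(seq)))
    return AlleleCatalog(alleles), SerogroupTable(groups)


def build_masking_catalog(
    config: SimConfig,
) -> tuple[AlleleCatalog, SerogroupTable, Genotype, str]:
    """Catalog with an engineered fully masked decoy, plus the genotype that
    triggers the pathology.

    The second allele of the first A serotype (the decoy, differing from its
    founder at two adjacent positions) has the region around its private
    substitutions copied into the first C-locus allele.  Every decoy-specific
    probe then also occurs in that C allele, so a sample homozygous for the
    founder and carrying the C allele lights up *all* of the decoy's probes:
    probe signals alone cannot distinguish founder/founder from
    founder/decoy.  Returns (catalog, serogroups, truth genotype, decoy name).
    """
    if config.n_loci < 3:
        raise ConfigError("masking construction needs at least loci A and C")
    catalog, groups = generate_allele_catalog(config)
    L = config.sequence_length
    max_len = 60
    base_allele = catalog.get("A*01:01")
    # locate the hypervariable columns of every locus (positions where group
    # members differ) and put the decoy's private variants as far from them
    # as possible, so the copied window cannot disturb any group's internal
    # structure
    def locus_columns(locus: str) -> np.ndarray:
        members = catalog.serotype_members(catalog.serotypes(locus)[0])
        s0 = np.frombuffer(members[0].sequence.encode(), dtype=np.uint8)
        cols: set[int] = set()
        for m in members[1:]:
            sm = np.frombuffer(m.sequence.encode(), dtype=np.uint8)
            cols.update(np.nonzero(s0 != sm)[0].tolist())
        return np.array(sorted(cols))

    c_columns = locus_columns("C")
    a_columns = locus_columns("A")
    centers = np.arange(max_len, L - max_len - 2)
    # the copied window must not contain a C column (it would collapse the C
    # group) and the decoy variants must not sit on an A column
    dist = np.min(np.abs(centers[:, None] - c_columns[None, :]), axis=1)
    dist[np.min(np.abs(centers[:, None] - a_columns[None, :]), axis=1) < 4] = -1
    center = int(centers[np.argmax(dist)])
    decoy_positions = (center, center + 1)
    decoy_seq = np.frombuffer(base_allele.sequence.encode(), dtype=np.uint8).copy()
    rng = np.random.default_rng(config.seed + 1)
    for p in decoy_positions:
        choices = _BASES[_BASES != decoy_seq[p]]
        decoy_seq[p] = rng.choice(choices)
    decoy_name = "A*01:02"
    # copy the decoy's variant neighbourhood into the whole C*01 group at the
    # same coordinates: every probe window overlapping the variants is then
    # shared with a present C allele, while the C group keeps its internal
    # column structure intact
    lo = max(0, decoy_positions[0] - (max_len - 1))
    hi = min(L, decoy_positions[-1] + 1 + max_len)
    new_alleles = []
    for a in catalog:
        if a.name == decoy_name:
            new_alleles.append(AlleleSequence(decoy_name, _to_str(decoy_seq)))
        elif a.serotype == "C*01":
            c_seq = np.frombuffer(a.sequence.encode(), dtype=np.uint8).copy()
            original = c_seq.copy()
            c_seq[lo:hi] = decoy_seq[lo:hi]
            # keep the group's own column variants intact
            inside = c_columns[(c_columns >= lo) & (c_columns < hi)]
            c_seq[inside] = original[inside]
            new_alleles.append(AlleleSequence(a.name, _to_str(c_seq)))
        else:
            new_alleles.append(a)
    truth: Genotype = {
        "A": ("A*01:01",),  # homozygous at the masked locus
        "B": ("B*01:01", "B*02:01"),
        "C": ("C*01:01", "C*02:01"),
    }
    return AlleleCatalog(new_alleles), groups, truth, decoy_name


# ---------------------------------------------------------------------------
# signal simulation
# ---------------------------------------------------------------------------

def _smooth_profile(n: int, sd: float, corr: float, rng: np.random.Generator) -> np.ndarray:
    """Lognormal hybridization-efficiency profile, smooth along the track."""
    z = rng.standard_normal(n)
    if corr > 0 and n > 1:
        z = gaussian_filter1d(z, sigma=corr, mode="nearest")
        s = z.std()
        if s > 0:
            z = z / s
    return np.exp(sd * z)


def simulate_array(
    genotype: Genotype,
    probeset: ProbeSet,
    catalog: AlleleCatalog,
    config: SimConfig,
    sample_seed: int,
    array_seed: int,
    scenario: str = "clean",
    array_id: str = "array",
    extra_genotype: Genotype | None = None,
) -> SimulatedSample:
    """Raw signals for one hybridization of a known genotype.

    ``sample_seed`` fixes the sample-level hybridization profile (shared by
    replicate arrays); ``array_seed`` fixes the per-array noise and scale.
    ``extra_genotype`` adds a second sample's material (the mixed scenario).
    """
    present: list[str] = []
    for locus, alleles in genotype.items():
        if len(set(alleles)) > 2 and scenario != "mixed":
            raise GenotypeError(f"locus {locus}: more than two alleles in a non-mixed sample")
        present.extend(alleles)
    if extra_genotype is not None:
        for alleles in extra_genotype.values():
            present.extend(alleles)
    present = sorted(set(present))
    for a in present:
        catalog.get(a)  # existence check

    profile_rng = np.random.default_rng(sample_seed)
    noise_rng = np.random.default_rng(array_seed)
    base = np.full(probeset.n_probes, config.negative_mean)
    for allele in present:  # sorted -> profile draws are order-stable
        pids = probeset.allele_probes[allele]
        profile = _smooth_profile(pids.size, config.profile_sd, config.profile_corr, profile_rng)
        np.add.at(base, pids, config.positive_mean * profile)
    noise = np.exp(noise_rng.normal(0.0, config.noise_sd, probeset.n_probes))
    scale = float(np.exp(noise_rng.normal(0.0, config.scale_sd)))
    if scenario == "degraded":
        scale *= config.degradation_factor
    values = base * noise * scale
    truth = {l: tuple(a) for l, a in genotype.items()}
    return SimulatedSample(array_id, truth, ArraySignals(array_id, "raw", values), scenario)


def draw_genotype(
    catalog: AlleleCatalog,
    rng: np.random.Generator,
    scenario: str = "clean",
) -> Genotype:
    """Random truth genotype for a scenario.

    'clean' heterozygotes draw two distinct serotypes per locus (one allele
    each); 'homozygous' makes one random locus single-allele; 'close-alleles'
    puts two alleles of one serotype at a random locus.
    """
    g: Genotype = {}
    loci = catalog.loci
    special = rng.integers(len(loci)) if scenario in ("homozygous", "close-alleles") else -1
    for i, locus in enumerate(loci):
        sts = catalog.serotypes(locus)
        if scenario == "homozygous" and i == special:
            st = sts[rng.integers(len(sts))]
            members = catalog.serotype_members(st)
            g[locus] = (members[rng.integers(len(members))].name,)
        elif scenario == "close-alleles" and i == special:
            st = sts[rng.integers(len(sts))]
            members = [a.name for a in catalog.serotype_members(st)]
            pick = rng.choice(len(members), size=2, replace=False)
            g[locus] = tuple(sorted(members[j] for j in pick))
        else:
            pick = rng.choice(len(sts), size=2, replace=False)
            chosen = []
            for j in pick:
                members = catalog.serotype_members(sts[j])
                chosen.append(members[rng.integers(len(members))].name)
            g[locus] = tuple(sorted(chosen))
    return g


def draw_disjoint_genotype(
    catalog: AlleleCatalog,
    rng: np.random.Generator,
    other: Genotype,
    max_tries: int = 100,
) -> Genotype:
    """A clean genotype sharing no allele with ``other``."""
    taken = {a for alleles in other.values() for a in alleles}
    for _ in range(max_tries):
        g = draw_genotype(catalog, rng)
        if not taken & {a for alleles in g.values() for a in alleles}:
            return g
    raise ConfigError("could not draw an allele-disjoint genotype")


SCENARIOS = (
    "clean",
    "replicate",
    "homozygous",
    "close-alleles",
    "degraded",
    "mixed",
    "negative-control",
)


def generate_dataset(
    config: SimConfig,
    n_samples: int,
    scenario_mix: dict[str, float] | None = None,
    probeset: ProbeSet | None = None,
    catalog: AlleleCatalog | None = None,
) -> tuple[AlleleCatalog, SerogroupTable, ProbeSet, list[SimulatedSample], pd.DataFrame]:
    """Reproducible cohort with a truth manifest.

    ``scenario_mix`` maps scenario name -> proportion (must sum to 1); the
    'replicate' proportion counts *pairs of arrays per slot* (each replicate
    slot emits two arrays of the same sample).  The manifest has one row per
    array: sample, scenario, truth alleles, replicate partner.
    """
    scenario_mix = scenario_mix or {"clean": 1.0}
    unknown = set(scenario_mix) - set(SCENARIOS)
    if unknown:
        raise ConfigError(f"unknown scenarios: {sorted(unknown)}")
    if abs(sum(scenario_mix.values()) - 1.0) > 1e-9:
        raise ConfigError("scenario proportions must sum to 1")
    serogroups = SerogroupTable({})
    if catalog is None:
        catalog, serogroups = generate_allele_catalog(config)
    if probeset is None:
        probeset = build_probe_set(catalog)
    rng = np.random.default_rng(config.seed + 1_000_003)
    # deterministic scenario assignment: largest-remainder apportionment
    names = sorted(scenario_mix)
    quotas = {s: scenario_mix[s] * n_samples for s in names}
    counts = {s: int(quotas[s]) for s in names}
    for s in sorted(names, key=lambda s: -(quotas[s] - counts[s])):
        if sum(counts.values()) >= n_samples:
            break
        counts[s] += 1
    samples: list[SimulatedSample] = []
    rows = []
    idx = 0
    for scenario in names:
        for _ in range(counts[scenario]):
            sample_id = f"S{idx:04d}"
            sample_seed = int(rng.integers(2**31))
            if scenario == "negative-control":
                genotype: Genotype = {l: () for l in catalog.loci}
                genotype = {}
                sim = SimulatedSample(
                    sample_id,
                    {},
                    simulate_array(
                        {}, probeset, catalog, config, sample_seed,
                        int(rng.integers(2**31)), scenario, sample_id,
                    ).signals,
                    scenario,
                )
                samples.append(sim)
                rows.append((sample_id, sample_id, scenario, "", ""))
                idx += 1
                continue
            base_scenario = "clean" if scenario in ("replicate", "degraded", "mixed") else scenario
            genotype = draw_genotype(catalog, rng, base_scenario)
            extra = None
            if scenario == "mixed":
                extra = draw_disjoint_genotype(catalog, rng, genotype)
            n_arrays = 2 if scenario == "replicate" else 1
            first_id = f"{sample_id}r0"
            for k in range(n_arrays):
                array_id = f"{sample_id}r{k}" if scenario == "replicate" else sample_id
                sim = simulate_array(
                    genotype, probeset, catalog, config, sample_seed,
                    int(rng.integers(2**31)), scenario, array_id, extra_genotype=extra,
                )
                sim.sample_id = sample_id
                if scenario == "replicate" and k == 1:
                    sim.replicate_of = first_id
                samples.append(sim)
                truth_str = ";".join(
                    a for locus in sorted(genotype) for a in genotype[locus]
                )
                if extra is not None:
                    truth_str += "+" + ";".join(
                        a for locus in sorted(extra) for a in extra[locus]
                    )
                rows.append(
                    (sample_id, array_id, scenario, truth_str, sim.replicate_of or "")
                )
            idx += 1
    manifest = pd.DataFrame(
        rows, columns=["sample_id", "array_id", "scenario", "truth_alleles", "replicate_of"]
    )
    return catalog, serogroups, probeset, samples, manifest
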