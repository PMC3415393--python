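"""Synthetic matched expression/genotype cohorts with planted plating errors.

The generator emulates the statistical structure the identity-QC method
relies on: cis-eQTL-driven expression (a linear shift per B allele plus
Gaussian noise), Hardy-Weinberg genotypes with Balding-Nichols population
divergence, optional parent-parent-child trios, tumour loss-of-
heterozygosity moderated by cellularity, and a taxonomy of plating errors
(neighbour swaps, k-cycles, sequence slippage over the pre-exclusion sample
sequence, plate swaps, 180-degree plate rotations, accidental duplicates,
alien samples and empty arrays).  Every cohort carries full per-stage plate
provenance so that error attribution and systematic plate-transform
searches are exercisable end to end.

All randomness flows from ``SimulationConfig.seed``; generation is
bit-reproducible for a fixed configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    Correction,
    ExpressionMatrix,
    GenotypeMatrix,
    Move,
    PLATE_N_COLS,
    PLATE_N_ROWS,
    PlateLayout,
    ProvenanceEntry,
    SampleMap,
    SampleRecord,
    apply_corrections,
    rc_to_well,
)

WELLS_PER_PLATE = PLATE_N_ROWS * PLATE_N_COLS
ARRAYS_PER_CHIP = 12

STAGE_EXTRACTION = "extraction"
STAGE_GENOTYPING = "genotyping"
STAGE_EXPRESSION = "expression_chip"


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PopulationGroup:
    """A study subpopulation.

    ``divergence`` is the Balding-Nichols drift parameter F: group allele
    frequencies are drawn from Beta(p(1-F)/F, (1-p)(1-F)/F) around the
    ancestral frequency p.  ``eqtl_active=False`` makes every cis-eQTL
    silent in the group, emulating associations that do not replicate
    across populations.
    """

    label: str
    proportion: float
    divergence: float = 0.0
    eqtl_active: bool = True


@dataclass(frozen=True)
class TumourSpec:
    """Tumour genotype distortion.

    A heterozygous germline call collapses to a homozygous call with
    probability ``loh_rate * cellularity``: the purer the tumour, the more
    loss-of-heterozygosity survives into the call; stromal contamination
    (low cellularity) rescues heterozygous calls.  Per-sample cellularity
    is Beta(cellularity_alpha, cellularity_beta) distributed.
    """

    loh_rate: float = 0.3
    cellularity_alpha: float = 5.0
    cellularity_beta: float = 2.0


# --- planted-error specifications ------------------------------------------


@dataclass(frozen=True)
class NeighbourSwap:
    """Swap the material of two samples adjacent in a platform's processing
    order (position chosen at random unless ``position`` is given)."""

    platform: str = "genotype"
    position: int | None = None


@dataclass(frozen=True)
class CycleError:
    """Cyclically permute the material of k samples on one platform."""

    k: int = 3
    platform: str = "genotype"
    samples: tuple[str, ...] | None = None


@dataclass(frozen=True)
class BlockReversal:
    """Reverse the order of ``length`` consecutive arrays in a platform's
    processing sequence (the 'order of four consecutive arrays was
    reversed' scenario)."""

    length: int = 4
    platform: str = "genotype"
    start: int | None = None


@dataclass(frozen=True)
class SlippageError:
    """Shift dispensing by one position over a window of the pre-exclusion
    extraction sequence: the genotype array intended for the included
    sample at sequence position q receives the sample at q+1.  Excluded
    space-holders inside the window become aliens; included samples whose
    predecessor is outside the window (or excluded) become orphans."""

    start: int | None = None  # 1-based extraction position
    length: int = 8


@dataclass(frozen=True)
class PlateSwapError:
    """Exchange the contents of two whole plates (same wells)."""

    platform: str = "genotype"
    plate_a: str | None = None
    plate_b: str | None = None


@dataclass(frozen=True)
class PlateRotationError:
    """Process one fully occupied plate rotated by 180 degrees."""

    platform: str = "genotype"
    plate_id: str | None = None


@dataclass(frozen=True)
class DuplicateError:
    """One sample's material ends up on a second array; the displaced
    sample is never plated."""

    platform: str = "genotype"


@dataclass(frozen=True)
class AlienError:
    """An excluded (space-holder) sample is plated onto an array intended
    for somebody else, who is never plated."""

    platform: str = "genotype"


@dataclass(frozen=True)
class EmptyArrayError:
    """An array is left with no sample hybridised to it."""

    platform: str = "expression"


ERROR_TYPES = (
    NeighbourSwap,
    CycleError,
    BlockReversal,
    SlippageError,
    PlateSwapError,
    PlateRotationError,
    DuplicateError,
    AlienError,
    EmptyArrayError,
)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror a 96-sample internal-pilot-sized study with strong
    cis-eQTL effects (one log2 unit per B allele against 0.3 s.d. residual
    noise), a third of probes carrying a true eQTL, and single-population
    structure; everything is overridable.
    """

    seed: int
    n_samples: int = 96
    n_excluded: int = 0
    excluded_positions: tuple[int, ...] | None = None  # 1-based sequence slots
    n_snps: int = 60
    n_probes: int = 150
    n_chromosomes: int = 6
    fraction_cis_eqtl: float = 1.0 / 3.0
    effect_size: float = 1.0
    noise_sd: float = 0.3
    baseline_mean: float = 7.5
    baseline_sd: float = 0.5
    intergenic_baseline: float = 5.0
    maf_range: tuple[float, float] = (0.1, 0.5)
    population_spec: tuple[PopulationGroup, ...] = (
        PopulationGroup("europe", 1.0, 0.0, True),
    )
    tumour_spec: TumourSpec | None = None
    n_trios: int = 0
    error_spec: tuple = ()
    fraction_probes_intergenic: float = 0.1
    fraction_eqtl_probes_snp_under: float = 0.5
    expression_order: str = "shuffled"  # or "sequence"
    missing_genotype_rate: float = 0.0

    def __post_init__(self) -> None:
        total = sum(g.proportion for g in self.population_spec)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group proportions must sum to 1, got {total}")
        for g in self.population_spec:
            if not 0.0 <= g.divergence < 1.0:
                raise ValueError("divergence F must lie in [0, 1)")
        if self.tumour_spec and not 0.0 <= self.tumour_spec.loh_rate <= 1.0:
            raise ValueError("loh_rate must lie in [0, 1]")


# ---------------------------------------------------------------------------
# population / genotypes


def _sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:03d}" for i in range(n)]


def simulate_population(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, pd.Series, list[tuple[str, str, str]]]:
    """Per-sample germline B-allele counts.

    Returns a genotype matrix whose columns are *sample* IDs (not arrays),
    the group label per sample, and the list of (father, mother, child)
    trios.  Within each group genotypes are Hardy-Weinberg at the group's
    drifted allele frequency; trio children obey Mendelian transmission.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_total = config.n_samples + config.n_excluded
    samples = _sample_ids(n_total)

    labels = [g.label for g in config.population_spec]
    props = np.array([g.proportion for g in config.population_spec])
    group_idx = rng.choice(len(labels), size=n_total, p=props)
    groups = pd.Series([labels[i] for i in group_idx], index=samples, name="group")

    lo, hi = config.maf_range
    ancestral = rng.uniform(lo, hi, size=config.n_snps)
    freqs = np.empty((len(labels), config.n_snps))
    for gi, grp in enumerate(config.population_spec):
        f = grp.divergence
        if f == 0.0:
            freqs[gi] = ancestral
        else:
            a = ancestral * (1 - f) / f
            b = (1 - ancestral) * (1 - f) / f
            freqs[gi] = rng.beta(a, b)

    p = freqs[group_idx]  # (n_total, n_snps)
    geno = rng.binomial(2, p).astype(float)

    trios: list[tuple[str, str, str]] = []
    if config.n_trios:
        if 3 * config.n_trios > n_total:
            raise ValueError("not enough samples for the requested trios")
        for t in range(config.n_trios):
            i0 = n_total - 3 * (t + 1)
            fa, mo, ch = i0, i0 + 1, i0 + 2
            groups.iloc[[mo, ch]] = groups.iloc[fa]
            gi = group_idx[fa]
            for par in (fa, mo):
                geno[par] = rng.binomial(2, freqs[gi])
            transmit = lambda g: rng.binomial(1, g / 2.0)  # noqa: E731
            geno[ch] = transmit(geno[fa]) + transmit(geno[mo])
            trios.append((samples[fa], samples[mo], samples[ch]))

    if config.missing_genotype_rate > 0:
        mask = rng.random(geno.shape) < config.missing_genotype_rate
        geno[mask] = np.nan

    snp_ids = [f"rs{i + 1:04d}" for i in range(config.n_snps)]
    per_chrom = int(np.ceil(config.n_snps / config.n_chromosomes))
    chroms, positions = [], []
    for i in range(config.n_snps):
        chroms.append(str(i // per_chrom + 1))
        positions.append(3_000_000 * (i % per_chrom) + 1_000_000)
    ann = pd.DataFrame({"chromosome": chroms, "position": positions}, index=snp_ids)
    values = pd.DataFrame(geno.T, index=snp_ids, columns=samples)
    return GenotypeMatrix(values, ann), groups, trios


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    geno: GenotypeMatrix,
    config: SimulationConfig,
    groups: pd.Series,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Per-sample expression profiles plus the truth table of true eQTLs.

    True-eQTL probes follow ``baseline + effect_size * B-count + noise``
    with the effect zeroed in groups whose eQTLs are inactive.  A
    configurable fraction of true-eQTL probes is annotated as covering SNPs
    (cis-eQTL artefact analogues); a fraction of null probes is annotated
    intergenic and given background-level intensities.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    samples = list(geno.values.columns)
    n_samples = len(samples)
    g_mat = geno.values.to_numpy().T  # samples x snps

    n_eqtl = int(round(config.fraction_cis_eqtl * config.n_probes))
    n_eqtl = min(n_eqtl, config.n_snps)
    eqtl_snp_idx = rng.choice(config.n_snps, size=n_eqtl, replace=False)

    probe_ids = [f"ILMN_{i + 1:05d}" for i in range(config.n_probes)]
    n_intergenic = int(round(config.fraction_probes_intergenic * config.n_probes))
    # layout of probe roles: true eQTL first, then intergenic, then null
    roles = ["eqtl"] * n_eqtl + ["intergenic"] * n_intergenic
    roles += ["null"] * (config.n_probes - len(roles))

    active = np.ones(n_samples, dtype=bool)
    inactive_groups = {g.label for g in config.population_spec if not g.eqtl_active}
    if inactive_groups:
        active = ~groups.loc[samples].isin(inactive_groups).to_numpy()

    snp_ann = geno.snp_annotation
    baselines = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_probes)
    values = np.empty((config.n_probes, n_samples))
    chroms, positions, tiers, n_under = [], [], [], []
    truth_rows = []
    snp_ids = list(geno.values.index)

    for pi, role in enumerate(roles):
        noise = rng.normal(0.0, config.noise_sd, size=n_samples)
        if role == "eqtl":
            si = int(eqtl_snp_idx[pi])
            dose = np.nan_to_num(g_mat[:, si], nan=1.0)
            e = baselines[pi] + config.effect_size * dose * active + noise
            chroms.append(snp_ann.iloc[si]["chromosome"])
            offset = int(rng.integers(-500_000, 500_000))
            positions.append(max(1, int(snp_ann.iloc[si]["position"]) + offset))
            tiers.append("perfect")
            covers = rng.random() < config.fraction_eqtl_probes_snp_under
            n_under.append(int(rng.integers(1, 4)) if covers else 0)
            truth_rows.append(
                {
                    "probe_id": probe_ids[pi],
                    "snp_id": snp_ids[si],
                    "effect_size": config.effect_size,
                    "n_snps_under_probe": n_under[-1],
                }
            )
        elif role == "intergenic":
            e = config.intergenic_baseline + noise
            chroms.append("un")
            positions.append(1)
            tiers.append("intergenic")
            n_under.append(0)
        else:  # null probe near a random SNP, eligible for the cis scan
            si = int(rng.integers(config.n_snps))
            e = baselines[pi] + noise
            chroms.append(snp_ann.iloc[si]["chromosome"])
            offset = int(rng.integers(-500_000, 500_000))
            positions.append(max(1, int(snp_ann.iloc[si]["position"]) + offset))
            tiers.append("perfect" if rng.random() < 0.8 else "good")
            n_under.append(0)
        values[pi] = e

    ann = pd.DataFrame(
        {
            "chromosome": chroms,
            "position": positions,
            "quality_tier": tiers,
            "n_snps_under_probe": n_under,
        },
        index=probe_ids,
    )
    expr = ExpressionMatrix(pd.DataFrame(values, index=probe_ids, columns=samples), ann)
    truth = pd.DataFrame(truth_rows, columns=["probe_id", "snp_id", "effect_size", "n_snps_under_probe"])
    return expr, truth


# ---------------------------------------------------------------------------
# tumour distortion


def apply_tumour_distortion(
    geno: GenotypeMatrix,
    spec: TumourSpec,
    rng: np.random.Generator,
    cellularity: float | np.ndarray | None = None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Collapse heterozygous calls toward homozygous on tumour material.

    Each heterozygous call collapses to 0 or 2 (equiprobably) with
    probability ``loh_rate * cellularity``; homozygous and missing calls
    are untouched.  Cellularity may be supplied per column, else drawn from
    the configured Beta distribution.  Returns the distorted matrix and the
    cellularities used.
    """
    vals = geno.values.to_numpy(dtype=float).copy()
    n_arrays = vals.shape[1]
    if cellularity is None:
        cellularity = rng.beta(spec.cellularity_alpha, spec.cellularity_beta, size=n_arrays)
    cellularity = np.broadcast_to(np.asarray(cellularity, dtype=float), (n_arrays,)).copy()

    het = vals == 1.0
    collapse_p = spec.loh_rate * cellularity[None, :]
    collapse = het & (rng.random(vals.shape) < collapse_p)
    direction = rng.integers(0, 2, size=vals.shape) * 2.0  # 0 or 2
    vals[collapse] = direction[collapse]
    out = GenotypeMatrix(
        pd.DataFrame(vals, index=geno.values.index, columns=geno.values.columns),
        geno.snp_annotation.copy(),
    )
    return out, cellularity


# ---------------------------------------------------------------------------
# provenance / layout construction


def _plate_positions(n: int, plate_prefix: str) -> list[tuple[str, str]]:
    """Sequence position -> (plate_id, well), filling plates row-major."""
    out = []
    for i in range(n):
        plate = f"{plate_prefix}{i // WELLS_PER_PLATE + 1}"
        idx = i % WELLS_PER_PLATE
        out.append((plate, rc_to_well(idx // PLATE_N_COLS, idx % PLATE_N_COLS)))
    return out


def _chip_positions(n: int, chip_prefix: str) -> list[tuple[str, str]]:
    """Expression chips hold 12 arrays in a single strip (wells A1-A12)."""
    out = []
    for i in range(n):
        chip = f"{chip_prefix}{i // ARRAYS_PER_CHIP + 1}"
        out.append((chip, rc_to_well(0, i % ARRAYS_PER_CHIP)))
    return out


def build_sample_map(config: SimulationConfig, rng: np.random.Generator) -> tuple[SampleMap, list[str]]:
    """Intended sample map with extraction, genotyping and expression-chip
    provenance.  Returns the map and the full pre-exclusion sequence."""
    n_total = config.n_samples + config.n_excluded
    samples = _sample_ids(n_total)

    if config.n_excluded:
        if config.excluded_positions is not None:
            excluded_pos = set(config.excluded_positions)
            if len(excluded_pos) != config.n_excluded:
                raise ValueError("excluded_positions inconsistent with n_excluded")
        else:
            excluded_pos = set(
                (rng.choice(n_total, size=config.n_excluded, replace=False) + 1).tolist()
            )
    else:
        excluded_pos = set()

    included = [s for i, s in enumerate(samples) if (i + 1) not in excluded_pos]

    extraction = _plate_positions(n_total, "XP")
    geno_pos = _plate_positions(len(included), "GP")
    if config.expression_order == "shuffled":
        expr_order = rng.permutation(len(included))
    elif config.expression_order == "sequence":
        expr_order = np.arange(len(included))
    else:
        raise ValueError(f"unknown expression_order {config.expression_order!r}")
    expr_slot_of = {included[si]: int(np.where(expr_order == si)[0][0]) for si in range(len(included))}
    expr_pos = _chip_positions(len(included), "EC")

    tissue = "tumour" if config.tumour_spec else "normal"
    records = []
    inc_rank = 0
    for i, s in enumerate(samples):
        seq = i + 1
        prov = [
            ProvenanceEntry(STAGE_EXTRACTION, "shared", extraction[i][0], extraction[i][1], seq)
        ]
        if seq in excluded_pos:
            records.append(SampleRecord(s, None, None, tissue, tuple(prov)))
            continue
        gp, gw = geno_pos[inc_rank]
        slot = expr_slot_of[s]
        ep, ew = expr_pos[slot]
        prov.append(ProvenanceEntry(STAGE_GENOTYPING, "genotype", gp, gw, inc_rank + 1))
        prov.append(ProvenanceEntry(STAGE_EXPRESSION, "expression", ep, ew, slot + 1))
        records.append(
            SampleRecord(s, f"E{inc_rank + 1:03d}", f"G{inc_rank + 1:03d}", tissue, tuple(prov))
        )
        inc_rank += 1
    return SampleMap(records), samples


# ---------------------------------------------------------------------------
# error injection


@dataclass
class CorruptionResult:
    actual_expression: dict[str, str | None]
    actual_genotype: dict[str, str | None]
    corrections: list[Correction]
    truth_map: SampleMap


def _stage_order(smap: SampleMap, platform: str) -> list[tuple[str, str]]:
    """(sample, array) in the platform stage's processing order."""
    entries = []
    for r in smap.records:
        arr = r.genotype_array if platform == "genotype" else r.expression_array
        if not arr:
            continue
        for p in r.provenance:
            if p.platform == platform:
                entries.append((p.position, r.sample_id, arr))
                break
    entries.sort()
    return [(s, a) for _, s, a in entries]


def _sequence_samples(smap: SampleMap) -> dict[int, str]:
    """Extraction position -> sample id over the pre-exclusion sequence."""
    seq = {}
    for r in smap.records:
        for p in r.provenance:
            if p.stage == STAGE_EXTRACTION and p.position is not None:
                seq[p.position] = r.sample_id
    return seq


def _stage_plates(smap: SampleMap, platform: str) -> dict[str, PlateLayout]:
    plates: dict[str, PlateLayout] = {}
    for r in smap.records:
        arr = r.genotype_array if platform == "genotype" else r.expression_array
        if not arr:
            continue
        for p in r.provenance:
            if p.platform == platform:
                lay = plates.setdefault(p.plate_id, PlateLayout.empty(p.plate_id))
                lay.set_well(p.well, r.sample_id)
    return plates


def inject_errors(
    smap: SampleMap,
    error_spec,
    rng: np.random.Generator,
) -> CorruptionResult:
    """Plant the configured errors and return the true assignment.

    The believed map is left untouched; what is returned is the *actual*
    contents of every array plus the ground-truth corrections that, applied
    to the believed map, reproduce the truth map exactly.
    """
    expr_of = {r.sample_id: r.expression_array for r in smap.records if r.expression_array}
    geno_of = {r.sample_id: r.genotype_array for r in smap.records if r.genotype_array}
    actual_e: dict[str, str | None] = {a: s for s, a in expr_of.items()}
    actual_g: dict[str, str | None] = {a: s for s, a in geno_of.items()}
    seq = _sequence_samples(smap)
    included = {r.sample_id for r in smap.records if r.expression_array or r.genotype_array}
    excluded_pool = [s for s in smap.sample_ids if s not in included]
    locked: set[tuple[str, str]] = set()  # (platform, sample)
    corrections: list[Correction] = []

    def arrays(platform):
        return actual_e if platform == "expression" else actual_g

    def intended_array(platform, s):
        return expr_of.get(s) if platform == "expression" else geno_of.get(s)

    def move(s, platform, new_array):
        """Post-state record row for sample s with one platform reassigned."""
        if platform == "genotype":
            return Move(s, expr_of.get(s), new_array)
        return Move(s, new_array, geno_of.get(s))

    def lock(platform, *ss):
        for s in ss:
            if (platform, s) in locked:
                raise ValueError(f"planted errors overlap on sample {s}")
            locked.add((platform, s))

    def free_pairs(platform):
        order = _stage_order(smap, platform)
        return [
            i
            for i in range(len(order) - 1)
            if (platform, order[i][0]) not in locked and (platform, order[i + 1][0]) not in locked
        ]

    for err in error_spec:
        if isinstance(err, NeighbourSwap):
            order = _stage_order(smap, err.platform)
            if err.position is not None:
                i = err.position
            else:
                cand = free_pairs(err.platform)
                if not cand:
                    raise ValueError("no free adjacent pair left for NeighbourSwap")
                i = int(rng.choice(cand))
            (s1, a1), (s2, a2) = order[i], order[i + 1]
            lock(err.platform, s1, s2)
            arrays(err.platform)[a1] = s2
            arrays(err.platform)[a2] = s1
            corrections.append(
                Correction(
                    "swap",
                    [move(s1, err.platform, a2), move(s2, err.platform, a1)],
                    platform=err.platform,
                    evidence={"stage_positions": [i, i + 1]},
                )
            )
        elif isinstance(err, CycleError):
            order = _stage_order(smap, err.platform)
            if err.samples is not None:
                chosen = list(err.samples)
            else:
                pool = [s for s, _ in order if (err.platform, s) not in locked]
                if len(pool) < err.k:
                    raise ValueError("not enough free samples for CycleError")
                chosen = [pool[j] for j in sorted(rng.choice(len(pool), err.k, replace=False))]
            lock(err.platform, *chosen)
            arrs = [intended_array(err.platform, s) for s in chosen]
            moves = []
            for i, a in enumerate(arrs):
                nxt = chosen[(i + 1) % err.k]
                arrays(err.platform)[a] = nxt
                moves.append(move(nxt, err.platform, a))
            corrections.append(
                Correction("swap" if err.k == 2 else "cycle", moves, platform=err.platform)
            )
        elif isinstance(err, BlockReversal):
            order = _stage_order(smap, err.platform)
            start = err.start if err.start is not None else int(
                rng.integers(0, len(order) - err.length + 1)
            )
            block = order[start : start + err.length]
            if any((err.platform, s) in locked for s, _ in block):
                raise ValueError("BlockReversal overlaps a planted error")
            lock(err.platform, *[s for s, _ in block])
            moves = []
            for (s_dst, a_dst), (s_src, _) in zip(block, reversed(block)):
                arrays(err.platform)[a_dst] = s_src
                moves.append(move(s_src, err.platform, a_dst))
            corrections.append(
                Correction(
                    "cycle",
                    moves,
                    platform=err.platform,
                    evidence={"transform": "block_reversal", "start": start, "length": err.length},
                )
            )
        elif isinstance(err, SlippageError):
            n_total = max(seq)

            def _tail_ok(b: int) -> bool:
                # the sample entering at the window end must not already own
                # an array outside the window (it would be duplicated)
                nxt = seq.get(b + 1)
                return nxt is None or nxt not in geno_of

            if err.start is not None:
                a0 = err.start
                b0 = min(a0 + err.length - 1, n_total)
                while b0 >= a0 and not _tail_ok(b0):
                    b0 -= 1
                if b0 < a0:
                    raise ValueError(
                        "slippage window must end at an excluded position or the sequence end"
                    )
            else:
                candidates = []
                for a0 in range(1, n_total - err.length + 2):
                    b0 = min(a0 + err.length - 1, n_total)
                    if _tail_ok(b0):
                        candidates.append((a0, b0))
                if not candidates:
                    raise ValueError(
                        "no slippage window ends at an excluded position; add excluded samples"
                    )
                a0, b0 = candidates[int(rng.integers(len(candidates)))]
            window = range(a0, b0 + 1)
            moves = []
            win_included = [q for q in window if seq[q] in geno_of]
            lock("genotype", *[seq[q] for q in win_included])
            for q in win_included:
                incoming = seq.get(q + 1)
                arr = geno_of[seq[q]]
                arrays("genotype")[arr] = incoming
                if incoming is not None:
                    moves.append(move(incoming, "genotype", arr))
            # orphans: included window samples not re-plated anywhere
            replated = {seq.get(q + 1) for q in win_included}
            for q in win_included:
                if seq[q] not in replated:
                    moves.append(move(seq[q], "genotype", None))
            corrections.append(
                Correction(
                    "slippage",
                    moves,
                    platform="genotype",
                    evidence={"window": [a0, b0], "shift": +1},
                )
            )
        elif isinstance(err, PlateSwapError):
            plates = _stage_plates(smap, err.platform)
            ids = sorted(plates)
            if err.plate_a is None or err.plate_b is None:
                if len(ids) < 2:
                    raise ValueError("PlateSwapError needs two plates")
                pa, pb = [ids[j] for j in rng.choice(len(ids), 2, replace=False)]
            else:
                pa, pb = err.plate_a, err.plate_b
            la, lb = plates[pa], plates[pb]
            if set(la.occupied_wells()) != set(lb.occupied_wells()):
                raise ValueError("plates must share an occupancy pattern to swap")
            moves = []
            for w in la.occupied_wells():
                sa, sb = la.sample_at(w), lb.sample_at(w)
                lock(err.platform, sa, sb)
                aa = intended_array(err.platform, sa)
                ab = intended_array(err.platform, sb)
                arrays(err.platform)[aa] = sb
                arrays(err.platform)[ab] = sa
                moves += [move(sb, err.platform, aa), move(sa, err.platform, ab)]
            corrections.append(
                Correction(
                    "plate_transform",
                    moves,
                    platform=err.platform,
                    evidence={"transform": "plate_swap", "plates": [pa, pb]},
                )
            )
        elif isinstance(err, PlateRotationError):
            plates = _stage_plates(smap, err.platform)
            full = [
                pid
                for pid, lay in sorted(plates.items())
                if len(lay.occupied_wells()) == WELLS_PER_PLATE
            ]
            pid = err.plate_id if err.plate_id is not None else (
                full[int(rng.integers(len(full)))] if full else None
            )
            if pid is None or len(plates[pid].occupied_wells()) != WELLS_PER_PLATE:
                raise ValueError("PlateRotationError needs a fully occupied plate")
            lay = plates[pid]
            rot = lay.rotate180()
            moves = []
            for w in lay.occupied_wells():
                s_intended = lay.sample_at(w)
                s_actual = rot.sample_at(w)
                lock(err.platform, s_intended)
                arrays(err.platform)[intended_array(err.platform, s_intended)] = s_actual
                moves.append(move(s_actual, err.platform, intended_array(err.platform, s_intended)))
            corrections.append(
                Correction(
                    "plate_transform",
                    moves,
                    platform=err.platform,
                    evidence={"transform": "rotation_180", "plate": pid},
                )
            )
        elif isinstance(err, DuplicateError):
            order = _stage_order(smap, err.platform)
            pool = [s for s, _ in order if (err.platform, s) not in locked]
            if len(pool) < 2:
                raise ValueError("not enough free samples for DuplicateError")
            s1, s2 = [pool[j] for j in sorted(rng.choice(len(pool), 2, replace=False))]
            lock(err.platform, s1, s2)
            a2 = intended_array(err.platform, s2)
            arrays(err.platform)[a2] = s1
            mv_keep = move(s1, err.platform, intended_array(err.platform, s1))
            mv_rep = (
                Move(s1, None, a2) if err.platform == "genotype" else Move(s1, a2, None)
            )
            corrections.append(
                Correction(
                    "duplicate",
                    [mv_keep, mv_rep, move(s2, err.platform, None)],
                    platform=err.platform,
                )
            )
        elif isinstance(err, AlienError):
            if not excluded_pool:
                raise ValueError("AlienError requires excluded samples (n_excluded > 0)")
            order = _stage_order(smap, err.platform)
            pool = [s for s, _ in order if (err.platform, s) not in locked]
            x = excluded_pool[int(rng.integers(len(excluded_pool)))]
            s = pool[int(rng.integers(len(pool)))]
            lock(err.platform, s)
            a = intended_array(err.platform, s)
            arrays(err.platform)[a] = x
            mv_alien = Move(x, None, a) if err.platform == "genotype" else Move(x, a, None)
            corrections.append(
                Correction("alien", [mv_alien, move(s, err.platform, None)], platform=err.platform)
            )
        elif isinstance(err, EmptyArrayError):
            order = _stage_order(smap, err.platform)
            pool = [s for s, _ in order if (err.platform, s) not in locked]
            s = pool[int(rng.integers(len(pool)))]
            lock(err.platform, s)
            a = intended_array(err.platform, s)
            arrays(err.platform)[a] = None
            corrections.append(
                Correction(
                    "empty",
                    [move(s, err.platform, None)],
                    platform=err.platform,
                    evidence={"array": a},
                )
            )
        else:
            raise TypeError(f"unknown error spec entry: {err!r}")

    truth_map = apply_corrections(smap, corrections, strict=False)
    # prune records for arrays that ended up empty
    empty_e = {a for a, s in actual_e.items() if s is None}
    empty_g = {a for a, s in actual_g.items() if s is None}
    for r in truth_map.records:
        if r.expression_array in empty_e:
            r.expression_array = None
        if r.genotype_array in empty_g:
            r.genotype_array = None
    return CorruptionResult(actual_e, actual_g, corrections, truth_map)


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class Cohort:
    config: SimulationConfig
    expr: ExpressionMatrix
    geno: GenotypeMatrix
    smap: SampleMap  # believed / intended
    truth_map: SampleMap
    truth_corrections: list[Correction]
    true_eqtls: pd.DataFrame
    groups: pd.Series
    trios: list[tuple[str, str, str]]
    sample_expression: ExpressionMatrix = None
    sample_genotypes: GenotypeMatrix = None


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Full synthetic cohort: believed map, corrupted array data, truth."""
    rng = np.random.default_rng(config.seed)
    geno_samples, groups, trios = simulate_population(config, rng)
    expr_samples, truth_eqtls = simulate_expression(geno_samples, config, groups, rng)
    smap, _ = build_sample_map(config, rng)
    corruption = inject_errors(smap, config.error_spec, rng)

    tumour_geno = None
    if config.tumour_spec:
        tumour_geno, _ = apply_tumour_distortion(geno_samples, config.tumour_spec, rng)

    def expr_column(sample):
        return expr_samples.values[sample].to_numpy()

    def geno_column(sample, tissue):
        src = tumour_geno if (tumour_geno is not None and tissue == "tumour") else geno_samples
        return src.values[sample].to_numpy()

    tissue_of = {r.sample_id: r.tissue for r in smap.records}
    e_arrays = sorted(corruption.actual_expression)
    g_arrays = sorted(corruption.actual_genotype)
    e_vals = np.full((config.n_probes, len(e_arrays)), np.nan)
    for j, a in enumerate(e_arrays):
        s = corruption.actual_expression[a]
        if s is not None:
            e_vals[:, j] = expr_column(s)
    g_vals = np.full((config.n_snps, len(g_arrays)), np.nan)
    for j, a in enumerate(g_arrays):
        s = corruption.actual_genotype[a]
        if s is not None:
            g_vals[:, j] = geno_column(s, tissue_of.get(s, "normal"))

    expr = ExpressionMatrix(
        pd.DataFrame(e_vals, index=expr_samples.values.index, columns=e_arrays),
        expr_samples.probe_annotation,
    )
    geno = GenotypeMatrix(
        pd.DataFrame(g_vals, index=geno_samples.values.index, columns=g_arrays),
        geno_samples.snp_annotation,
    )
    return Cohort(
        config=config,
        expr=expr,
        geno=geno,
        smap=smap,
        truth_map=corruption.truth_map,
        truth_corrections=corruption.corrections,
        true_eqtls=truth_eqtls,
        groups=groups,
        trios=trios,
        sample_expression=expr_samples,
        sample_genotypes=geno_samples,
    )


# ---------------------------------------------------------------------------
# special-purpose cohorts


@dataclass
class QuartetCohort:
    """Matched tumour/normal genotype + expression quartets per sample."""

    expr: ExpressionMatrix
    geno: GenotypeMatrix
    samples: list[str]
    expr_arrays: dict[str, dict[str, str]]  # sample -> {"tumour": ..., "normal": ...}
    geno_arrays: dict[str, dict[str, str]]
    true_eqtls: pd.DataFrame
    cellularity: pd.Series


def simulate_tumour_quartets(config: SimulationConfig) -> QuartetCohort:
    """Per sample: normal + tumour expression arrays (both driven by the
    germline genotype) and normal + tumour genotype arrays (the tumour one
    LOH-distorted).  Used to study the direction of tumour-induced score
    degradation."""
    spec = config.tumour_spec or TumourSpec()
    rng = np.random.default_rng(config.seed)
    geno_samples, groups, _ = simulate_population(config, rng)
    expr_n, truth = simulate_expression(geno_samples, config, groups, rng)
    # second expression replicate with independent noise for the tumour arm
    expr_t, _ = simulate_expression(geno_samples, config, groups, rng)
    tumour_geno, cellularity = apply_tumour_distortion(geno_samples, spec, rng)

    samples = list(geno_samples.values.columns)
    e_cols, e_ids = [], []
    g_cols, g_ids = [], []
    expr_arrays, geno_arrays = {}, {}
    for i, s in enumerate(samples):
        ids = {"normal": f"EN{i + 1:03d}", "tumour": f"ET{i + 1:03d}"}
        expr_arrays[s] = ids
        e_ids += [ids["normal"], ids["tumour"]]
        e_cols += [expr_n.values[s].to_numpy(), expr_t.values[s].to_numpy()]
        gids = {"normal": f"GN{i + 1:03d}", "tumour": f"GT{i + 1:03d}"}
        geno_arrays[s] = gids
        g_ids += [gids["normal"], gids["tumour"]]
        g_cols += [geno_samples.values[s].to_numpy(), tumour_geno.values[s].to_numpy()]

    expr = ExpressionMatrix(
        pd.DataFrame(np.column_stack(e_cols), index=expr_n.values.index, columns=e_ids),
        expr_n.probe_annotation,
    )
    geno = GenotypeMatrix(
        pd.DataFrame(np.column_stack(g_cols), index=geno_samples.values.index, columns=g_ids),
        geno_samples.snp_annotation,
    )
    return QuartetCohort(
        expr, geno, samples, expr_arrays, geno_arrays, truth,
        pd.Series(cellularity, index=samples),
    )


def degrade_arrays(
    expr: ExpressionMatrix,
    array_ids: list[str],
    rng: np.random.Generator,
    severity: float | list[float] = 1.0,
    background_level: float = 4.8,
    background_sd: float = 0.1,
    intergenic_excess: float = 0.5,
) -> ExpressionMatrix:
    """Degrade arrays towards signal-free background.

    ``severity`` (0-1, scalar or per array) mixes the original signal with
    a narrow background band; at severity 1 nothing but background
    remains.  Intergenic probes sit slightly above the band
    (cross-hybridisation background dominates once real signal is gone,
    which is why rank separation goes negative, not to zero, on failed or
    empty arrays)."""
    values = expr.values.copy()
    sev = np.broadcast_to(np.asarray(severity, dtype=float), (len(array_ids),))
    intergenic = (
        (expr.probe_annotation["quality_tier"] == "intergenic")
        .reindex(values.index, fill_value=False)
        .to_numpy()
    )
    for a, s in zip(array_ids, sev):
        noise = rng.normal(background_level, background_sd, size=len(values))
        noise[intergenic] += intergenic_excess * s
        values[a] = (1.0 - s) * values[a] + s * noise
    return ExpressionMatrix(values, expr.probe_annotation)
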