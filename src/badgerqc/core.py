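"""Shared domain containers for expression/genotype identity QC.

The central objects are an expression matrix (log2 intensities, probes x
arrays), a genotype matrix (B-allele counts in {0, 1, 2} with missing values,
SNPs x arrays), and a sample map tying sample IDs to the arrays they were
intended to be hybridised on, together with per-stage plate/well provenance.
Missing values are encoded uniformly as NaN in float-valued matrices, a
sentinel distinct from the valid count 0.

Coordinates are 1-based base pairs; plate wells use row letters A-H and
1-based columns 1-12 with A1 at the top left.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = np.nan

QUALITY_TIERS = ("perfect", "good", "other", "intergenic")
SEXES = ("male", "female", "unknown")

PLATE_ROWS = "ABCDEFGH"
PLATE_N_ROWS = 8
PLATE_N_COLS = 12

_WELL_RE = re.compile(r"^([A-H])([0-9]{1,2})$")


def well_to_rc(well: str) -> tuple[int, int]:
    """Parse a well label like ``"A1"`` into 0-based (row, column)."""
    m = _WELL_RE.match(well)
    if not m:
        raise ValueError(f"malformed well label: {well!r}")
    col = int(m.group(2))
    if not 1 <= col <= PLATE_N_COLS:
        raise ValueError(f"well column out of range 1-12: {well!r}")
    return PLATE_ROWS.index(m.group(1)), col - 1


def rc_to_well(row: int, col: int) -> str:
    """Format 0-based (row, column) as a well label."""
    if not (0 <= row < PLATE_N_ROWS and 0 <= col < PLATE_N_COLS):
        raise ValueError(f"well coordinates out of range: ({row}, {col})")
    return f"{PLATE_ROWS[row]}{col + 1}"


def is_valid_well(well: str) -> bool:
    try:
        well_to_rc(well)
    except ValueError:
        return False
    return True


def _check_unique(ids, what: str) -> list[str]:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dups = set(), set()
        for i in ids:
            if i in seen:
                dups.add(i)
            seen.add(i)
        return [f"duplicate {what}: {sorted(dups)}"]
    return []


@dataclass
class ExpressionMatrix:
    """Log2-intensity values, probes (rows) x expression arrays (columns).

    ``probe_annotation`` is indexed by probe ID with columns ``chromosome``,
    ``position`` (1-based bp), ``quality_tier`` (one of
    :data:`QUALITY_TIERS`) and ``n_snps_under_probe`` (number of known SNPs
    covered by the probe sequence; probes covering SNPs give rise to
    cis-eQTL artefacts, a robust identity signal).
    """

    values: pd.DataFrame
    probe_annotation: pd.DataFrame

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.values.columns)

    def validate(self) -> list[str]:
        issues = []
        issues += _check_unique(self.values.index, "probe id")
        issues += _check_unique(self.values.columns, "expression array id")
        vals = self.values.to_numpy(dtype=float)
        if np.isinf(vals).any():
            issues.append("expression values must be finite or missing")
        missing = set(self.values.index) - set(self.probe_annotation.index)
        if missing:
            issues.append(f"probes without annotation: {sorted(missing)[:5]}")
        else:
            ann = self.probe_annotation.loc[self.values.index]
            bad_tier = set(ann["quality_tier"]) - set(QUALITY_TIERS)
            if bad_tier:
                issues.append(f"unknown quality tiers: {sorted(bad_tier)}")
            if (ann["n_snps_under_probe"].to_numpy() < 0).any():
                issues.append("n_snps_under_probe must be non-negative")
        return issues

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.values.equals(other.values) and self.probe_annotation.equals(
            other.probe_annotation
        )


@dataclass
class GenotypeMatrix:
    """Observed B-allele counts, SNPs (rows) x genotype arrays (columns).

    Entries are 0, 1, 2 or NaN (missing).  Only three genotypes (AA, AB, BB)
    are represented, a diploid assumption that tumour samples may violate;
    :func:`badgerqc.simulate.apply_tumour_distortion` models the consequences.
    ``snp_annotation`` is indexed by SNP ID with columns ``chromosome`` and
    ``position`` (1-based bp).
    """

    values: pd.DataFrame
    snp_annotation: pd.DataFrame

    @property
    def snp_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def array_ids(self) -> list[str]:
        return list(self.values.columns)

    def validate(self) -> list[str]:
        issues = []
        issues += _check_unique(self.values.index, "snp id")
        issues += _check_unique(self.values.columns, "genotype array id")
        vals = self.values.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = sorted(set(vals[~ok].tolist()))
            issues.append(f"genotype values outside {{0,1,2,missing}}: {bad[:5]}")
        missing = set(self.values.index) - set(self.snp_annotation.index)
        if missing:
            issues.append(f"SNPs without annotation: {sorted(missing)[:5]}")
        return issues

    def equals(self, other: "GenotypeMatrix") -> bool:
        return self.values.equals(other.values) and self.snp_annotation.equals(
            other.snp_annotation
        )


@dataclass(frozen=True)
class ProvenanceEntry:
    """Location of a sample at one processing stage.

    ``platform`` tags the stage as belonging to the expression or genotype
    arm of the experiment (or ``"shared"`` for pre-split stages such as
    extraction); ``position`` is the ordinal of the sample in the stage's
    processing sequence, which makes sequence-slippage hypotheses
    well-defined.
    """

    stage: str
    platform: str  # "expression" | "genotype" | "shared"
    plate_id: str
    well: str
    position: int | None = None


@dataclass
class SampleRecord:
    sample_id: str
    expression_array: str | None = None
    genotype_array: str | None = None
    tissue: str = "tumour"
    provenance: tuple[ProvenanceEntry, ...] = ()

    def copy(self) -> "SampleRecord":
        return replace(self)


@dataclass
class SampleMap:
    """Intended mapping of samples to arrays, with plate provenance.

    A sample may appear in several records (replicate arrays); samples with
    no arrays at all are representable too and carry the pre-exclusion
    sequence information needed to resolve slippage errors.
    """

    records: list[SampleRecord] = field(default_factory=list)

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.sample_id, None)
        return list(seen)

    @property
    def expression_arrays(self) -> list[str]:
        return [r.expression_array for r in self.records if r.expression_array]

    @property
    def genotype_arrays(self) -> list[str]:
        return [r.genotype_array for r in self.records if r.genotype_array]

    @property
    def l(self) -> int:  # noqa: E743 - the field's own symbol
        return len(set(self.expression_arrays))

    @property
    def m(self) -> int:
        return len(set(self.genotype_arrays))

    @property
    def n_matched(self) -> int:
        return len(self.matched_pairs())

    def matched_pairs(self) -> list[tuple[str, str, str]]:
        """(sample_id, expression_array, genotype_array) for intended matches."""
        return [
            (r.sample_id, r.expression_array, r.genotype_array)
            for r in self.records
            if r.expression_array and r.genotype_array
        ]

    def sample_of_expression(self) -> dict[str, str]:
        return {r.expression_array: r.sample_id for r in self.records if r.expression_array}

    def sample_of_genotype(self) -> dict[str, str]:
        return {r.genotype_array: r.sample_id for r in self.records if r.genotype_array}

    def record_of(self, sample_id: str) -> SampleRecord | None:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        return None

    def replicate_genotype_counts(self) -> dict[str, int]:
        """Samples intended on more than one genotype array (drives g in the
        gap statistic)."""
        counts: dict[str, int] = {}
        for r in self.records:
            if r.genotype_array:
                counts[r.sample_id] = counts.get(r.sample_id, 0) + 1
        return {s: c for s, c in counts.items() if c > 1}

    def provenance_of(self, sample_id: str) -> tuple[ProvenanceEntry, ...]:
        for r in self.records:
            if r.sample_id == sample_id and r.provenance:
                return r.provenance
        return ()

    def stage_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            for p in r.provenance:
                seen.setdefault(p.stage, None)
        return list(seen)

    def copy(self) -> "SampleMap":
        return SampleMap([r.copy() for r in self.records])

    def validate(self) -> list[str]:
        issues = []
        for arrs, what in (
            (self.expression_arrays, "expression array"),
            (self.genotype_arrays, "genotype array"),
        ):
            issues += _check_unique(arrs, what)
        for r in self.records:
            for p in r.provenance:
                if not is_valid_well(p.well):
                    issues.append(
                        f"sample {r.sample_id}: malformed well {p.well!r} at stage {p.stage}"
                    )
        return [i for i in issues if i]

    def flags(self) -> list[str]:
        """Informational flags (not errors): replicate arrays etc."""
        return [
            f"replicate genotype arrays for sample {s} (x{c})"
            for s, c in self.replicate_genotype_counts().items()
        ]

    def assignment_signature(self) -> frozenset[tuple[str, str, str]]:
        """Canonical (sample, platform, array) set for map comparisons."""
        sig = set()
        for r in self.records:
            if r.expression_array:
                sig.add((r.sample_id, "expression", r.expression_array))
            if r.genotype_array:
                sig.add((r.sample_id, "genotype", r.genotype_array))
        return frozenset(sig)


# ---------------------------------------------------------------------------
# score / rank containers


@dataclass
class ScoreMatrix:
    """Matrix of identity scores B, expression arrays (rows) x genotype
    arrays (columns).

    ``scores`` holds the missing-rescaled sums of squared differences between
    predicted and observed B-allele counts (smaller = better match);
    ``n_eqtls_used`` the per-cell count of non-missing terms; ``sum_sq`` the
    raw unscaled sums.
    """

    scores: pd.DataFrame
    n_eqtls_used: pd.DataFrame
    n_eqtls_total: int
    sum_sq: pd.DataFrame

    @property
    def expression_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def genotype_ids(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class RankMatrix:
    """Per-expression-array ranks of the scores; 1 = best match, ties share
    the minimum rank (exact duplicate genotype arrays must all be rank 1)."""

    ranks: pd.DataFrame


@dataclass
class DeltaStat:
    """Order statistics of one expression array's score row.

    ``gap`` is B_(g+1) - B_(1) where g is the largest number of replicate
    genotype arrays expected in the study; a large gap means the best match
    is well separated from the bulk and hence trustworthy.  ``min_score`` on
    its own indicates whether any matching genotype array exists at all.
    """

    expression_array_id: str
    g: int
    min_score: float
    gap: float
    order_stats: np.ndarray
    best_genotype_array: str | None = None


# ---------------------------------------------------------------------------
# plates


@dataclass
class PlateLayout:
    """An 8x12 plate: well -> (sample or empty, sex)."""

    plate_id: str
    samples: np.ndarray  # (8, 12) object array, None = empty well
    sexes: np.ndarray  # (8, 12) object array of SEXES entries or None

    @classmethod
    def empty(cls, plate_id: str) -> "PlateLayout":
        return cls(
            plate_id,
            np.full((PLATE_N_ROWS, PLATE_N_COLS), None, dtype=object),
            np.full((PLATE_N_ROWS, PLATE_N_COLS), None, dtype=object),
        )

    @classmethod
    def from_sex_grid(cls, plate_id: str, sexes: np.ndarray) -> "PlateLayout":
        lay = cls.empty(plate_id)
        lay.sexes = np.asarray(sexes, dtype=object)
        if lay.sexes.shape != (PLATE_N_ROWS, PLATE_N_COLS):
            raise ValueError("sex grid must be 8x12")
        return lay

    def set_well(self, well: str, sample_id: str | None, sex: str = "unknown") -> None:
        r, c = well_to_rc(well)
        self.samples[r, c] = sample_id
        self.sexes[r, c] = sex

    def sample_at(self, well: str) -> str | None:
        r, c = well_to_rc(well)
        return self.samples[r, c]

    def occupied_wells(self) -> list[str]:
        return [
            rc_to_well(r, c)
            for r in range(PLATE_N_ROWS)
            for c in range(PLATE_N_COLS)
            if self.samples[r, c] is not None
        ]

    def rotate180(self) -> "PlateLayout":
        return PlateLayout(
            self.plate_id, self.samples[::-1, ::-1].copy(), self.sexes[::-1, ::-1].copy()
        )

    def reverse_rows(self) -> "PlateLayout":
        return PlateLayout(self.plate_id, self.samples[::-1, :].copy(), self.sexes[::-1, :].copy())

    def reverse_columns(self) -> "PlateLayout":
        return PlateLayout(self.plate_id, self.samples[:, ::-1].copy(), self.sexes[:, ::-1].copy())

    def sexes_equal(self, other: "PlateLayout") -> bool:
        return bool(np.array_equal(self.sexes, other.sexes))

    def sex_inverse(self) -> "PlateLayout":
        flip = {"male": "female", "female": "male"}
        inv = np.array(
            [[flip.get(s, s) for s in row] for row in self.sexes], dtype=object
        )
        return PlateLayout(self.plate_id, self.samples.copy(), inv)

    def equals(self, other: "PlateLayout") -> bool:
        return (
            self.plate_id == other.plate_id
            and np.array_equal(self.samples, other.samples)
            and np.array_equal(self.sexes, other.sexes)
        )


# ---------------------------------------------------------------------------
# corrections / reports


CORRECTION_KINDS = (
    "swap",
    "cycle",
    "chain",
    "slippage",
    "plate_transform",
    "duplicate",
    "alien",
    "orphan",
    "empty",
)


@dataclass(frozen=True)
class Move:
    """Post-correction assignment for one sample (one map record)."""

    sample_id: str
    expression_array: str | None
    genotype_array: str | None


@dataclass
class Correction:
    kind: str
    moves: list[Move] = field(default_factory=list)
    platform: str = "undetermined"  # attributed platform
    evidence: dict = field(default_factory=dict)

    def affected_samples(self) -> set[str]:
        return {m.sample_id for m in self.moves}

    def affected_arrays(self) -> set[tuple[str, str]]:
        arrs = set()
        for m in self.moves:
            if m.expression_array:
                arrs.add(("expression", m.expression_array))
            if m.genotype_array:
                arrs.add(("genotype", m.genotype_array))
        return arrs


@dataclass
class MixupReport:
    corrections: list[Correction] = field(default_factory=list)
    unresolved: list[dict] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def apply_corrections(
    smap: SampleMap, corrections: list[Correction], strict: bool = True
) -> SampleMap:
    """Apply a set of corrections, returning a new map.

    Each correction's moves encode the complete post-correction records for
    every affected sample.  Corrections must be disjoint on samples and
    arrays; applying the result must leave every array assigned at most
    once (checked when ``strict``).
    """
    seen_samples: set[str] = set()
    seen_arrays: set[tuple[str, str]] = set()
    for corr in corrections:
        s = corr.affected_samples()
        a = corr.affected_arrays()
        if seen_samples & s or seen_arrays & a:
            raise ValueError("overlapping corrections: none can be applied safely")
        seen_samples |= s
        seen_arrays |= a

    original: dict[str, SampleRecord] = {}
    for r in smap.records:
        original.setdefault(r.sample_id, r)

    new_records = [r.copy() for r in smap.records if r.sample_id not in seen_samples]
    for corr in corrections:
        for mv in corr.moves:
            proto = original.get(mv.sample_id)
            new_records.append(
                SampleRecord(
                    sample_id=mv.sample_id,
                    expression_array=mv.expression_array,
                    genotype_array=mv.genotype_array,
                    tissue=proto.tissue if proto else "tumour",
                    provenance=proto.provenance if proto else (),
                )
            )
    out = SampleMap(new_records)
    if strict:
        for arrs, what in (
            (out.expression_arrays, "expression array"),
            (out.genotype_arrays, "genotype array"),
        ):
            dup = _check_unique(arrs, what)
            if dup:
                raise ValueError(f"corrections yield an inconsistent map: {dup}")
    return out


# ---------------------------------------------------------------------------
# validation across inputs


def validate_inputs(
    expr: ExpressionMatrix, geno: GenotypeMatrix, smap: SampleMap
) -> list[str]:
    """Cross-check the three inputs; returns a list of human-readable issues
    (empty iff everything referenced exists and all invariants hold)."""
    issues = expr.validate() + geno.validate()
    # map-level structural problems (replicates are informational flags)
    issues += smap.validate()
    expr_ids = set(expr.array_ids)
    geno_ids = set(geno.array_ids)
    for r in smap.records:
        if r.expression_array and r.expression_array not in expr_ids:
            issues.append(
                f"sample {r.sample_id}: unknown expression array {r.expression_array!r}"
            )
        if r.genotype_array and r.genotype_array not in geno_ids:
            issues.append(
                f"sample {r.sample_id}: unknown genotype array {r.genotype_array!r}"
            )
    return issues
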