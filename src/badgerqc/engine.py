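"""Core identity statistics: genotype prediction, score and rank matrices,
eQTL refinement, the gap statistic, and the iterative correction loop.

Given per-genotype expression densities f_AA, f_AB, f_BB for an eQTL and an
expression level e, the posterior over genotype classes under equal priors
is f_g(e) / sum_g' f_g'(e), and the predicted B-allele count is the
posterior expectation p = P(AB|e) + 2 P(BB|e).  As the expression signal
fades the prediction tends to 1 (the heterozygote), which conveniently
under-penalises the error mode most likely to be innocent (het/hom
miscalls) in the squared-difference score.

The score between expression array j and genotype array k sums, over the
eQTL set, the squared difference between predicted and observed B-allele
counts.  Under missing data the sum is rescaled by I/I_jk (I = eQTLs in the
set, I_jk = non-missing terms for the cell), reducing to the plain sum when
nothing is missing.  Matching works from expression arrays towards
genotype arrays: ranks are computed within each expression array's row, and
the intended partner of a correctly mapped array should be rank 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import rankdata

from .core import (
    Correction,
    DeltaStat,
    ExpressionMatrix,
    GenotypeMatrix,
    MixupReport,
    RankMatrix,
    SampleMap,
    ScoreMatrix,
    apply_corrections,
)
from .eqtl import EQTLPair, fit_eqtl_set, scan_cis_associations

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# prediction


def predict_b_allele(pair: EQTLPair, e: float) -> tuple[float, dict[int, float] | None]:
    """Posterior-expected B-allele count for one expression level.

    Unavailable classes contribute nothing and the posterior renormalises
    over the available ones (equal priors over observable classes).  A
    missing expression value yields a missing prediction.
    """
    if not pair.densities:
        raise ValueError(f"eQTL pair {pair.key} has no available class density")
    if e is None or (isinstance(e, float) and np.isnan(e)):
        return float("nan"), None
    classes = sorted(pair.densities)
    logf = np.array([pair.densities[c].logpdf(e)[0] for c in classes])
    post = np.exp(logf - logsumexp(logf))
    posterior = {c: float(p) for c, p in zip(classes, post)}
    p = float(np.dot(classes, post))
    return p, posterior


def predict_matrix(pairs: list[EQTLPair], expr: ExpressionMatrix) -> pd.DataFrame:
    """Predicted B-allele counts, expression arrays (rows) x eQTLs (cols)."""
    cols = {}
    for pair in pairs:
        e = expr.values.loc[pair.probe_id].to_numpy(dtype=float)
        classes = sorted(pair.densities)
        logf = np.full((len(classes), len(e)), -np.inf)
        ok = ~np.isnan(e)
        for ci, c in enumerate(classes):
            if ok.any():
                logf[ci, ok] = pair.densities[c].logpdf(e[ok])
        with np.errstate(invalid="ignore"):
            post = np.exp(logf - logsumexp(logf, axis=0, keepdims=True))
        p = np.array(classes, dtype=float) @ post
        p[~ok] = np.nan
        cols[pair.key] = p
    out = pd.DataFrame(cols, index=expr.array_ids)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["probe_id", "snp_id"])
    return out


def observed_matrix(pairs: list[EQTLPair], geno: GenotypeMatrix) -> pd.DataFrame:
    """Observed B-allele counts, eQTLs (rows) x genotype arrays (cols)."""
    rows = {p.key: geno.values.loc[p.snp_id].to_numpy(dtype=float) for p in pairs}
    out = pd.DataFrame.from_dict(rows, orient="index", columns=geno.array_ids)
    out.index = pd.MultiIndex.from_tuples(out.index, names=["probe_id", "snp_id"])
    return out


# ---------------------------------------------------------------------------
# scores and ranks


def score_matrix(predicted: pd.DataFrame, observed: pd.DataFrame) -> ScoreMatrix:
    """Missing-rescaled sum of squared prediction errors per array pair.

    ``predicted`` is l x I (expression arrays x eQTLs), ``observed`` I x m.
    Cells with no jointly non-missing eQTL are missing and excluded from
    ranking.
    """
    if not predicted.columns.equals(observed.index):
        observed = observed.loc[predicted.columns]
    P = predicted.to_numpy(dtype=float)
    O = observed.to_numpy(dtype=float)
    n_eqtls = P.shape[1]

    Pm = ~np.isnan(P)
    Om = ~np.isnan(O)
    Pf = np.nan_to_num(P)
    Of = np.nan_to_num(O)

    sum_sq = (Pf * Pf) @ Om + Pm @ (Of * Of) - 2.0 * (Pf @ Of)
    np.maximum(sum_sq, 0.0, out=sum_sq)
    counts = Pm.astype(np.int64) @ Om.astype(np.int64)

    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(counts > 0, n_eqtls / np.maximum(counts, 1) * sum_sq, np.nan)

    idx = predicted.index
    cols = observed.columns
    return ScoreMatrix(
        scores=pd.DataFrame(scores, index=idx, columns=cols),
        n_eqtls_used=pd.DataFrame(counts, index=idx, columns=cols),
        n_eqtls_total=n_eqtls,
        sum_sq=pd.DataFrame(sum_sq, index=idx, columns=cols),
    )


def rank_matrix(score: ScoreMatrix) -> RankMatrix:
    """Per-row ranks of the scores; 1 = best, ties take the minimum rank so
    that exact duplicate genotype arrays are all rank 1."""
    vals = score.scores.to_numpy(dtype=float)
    ranks = np.full(vals.shape, np.nan)
    for i, row in enumerate(vals):
        ok = ~np.isnan(row)
        if not ok.any():
            continue
        ranks[i, ok] = rankdata(row[ok], method="min")
    return RankMatrix(pd.DataFrame(ranks, index=score.scores.index, columns=score.scores.columns))


def delta_statistic(score_row: pd.Series, g: int = 1) -> DeltaStat:
    """Gap statistic for one expression array: B_(g+1) - B_(1).

    ``g`` is the largest number of replicate genotype arrays expected, so
    the gap is measured past any block of replicates that legitimately
    share a near-minimal score.
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    row = score_row.dropna()
    if len(row) <= g:
        raise ValueError(f"need more than g={g} non-missing scores, got {len(row)}")
    order = np.sort(row.to_numpy(dtype=float))
    best = row.idxmin()
    return DeltaStat(
        expression_array_id=str(score_row.name) if score_row.name is not None else "",
        g=g,
        min_score=float(order[0]),
        gap=float(order[g] - order[0]),
        order_stats=order,
        best_genotype_array=str(best),
    )


def delta_statistics(score: ScoreMatrix, g: int = 1) -> dict[str, DeltaStat]:
    out = {}
    for a in score.expression_ids:
        row = score.scores.loc[a]
        if row.notna().sum() > g:
            out[a] = delta_statistic(row, g)
    return out


# ---------------------------------------------------------------------------
# refinement


def eqtl_discrepancy(
    predicted: pd.DataFrame,
    observed: pd.DataFrame,
    matched_pairs: list[tuple[str, str]],
) -> pd.Series:
    """Per-eQTL mean squared residual over well-matched array pairs.

    ``matched_pairs`` lists (expression array, genotype array) pairs
    believed to be correctly mapped.  eQTLs with no usable pair are NaN
    (to be dropped by the caller).
    """
    if not matched_pairs:
        raise ValueError("need at least one well-matched array pair")
    e_ids = [p[0] for p in matched_pairs]
    g_ids = [p[1] for p in matched_pairs]
    P = predicted.loc[e_ids].to_numpy(dtype=float)  # pairs x eqtls
    O = observed.loc[:, g_ids].to_numpy(dtype=float).T
    sq = (P - O) ** 2
    with np.errstate(invalid="ignore"):
        d = np.nanmean(sq, axis=0)
    return pd.Series(d, index=predicted.columns)


def auto_discrepancy_cutoff(d: pd.Series, min_prominence: float = 10.0) -> float:
    """Cutoff at the largest gap in the sorted discrepancies.

    Only gaps whose upper edge lies above the median are candidates (the
    cutoff separates a poorly performing tail, never the heart of the
    set), and the winning gap must be prominent (>= ``min_prominence``
    times the mean inter-point gap).  Otherwise no cutoff is applied
    (returns +inf): a homogeneous set of well-behaved eQTLs should not be
    split.
    """
    vals = np.sort(d.dropna().to_numpy(dtype=float))
    if len(vals) < 4:
        return float("inf")
    gaps = np.diff(vals)
    mean_gap = gaps.mean()
    if mean_gap <= 0:
        return float("inf")
    med = float(np.median(vals))
    candidates = np.flatnonzero(vals[1:] > med)
    i = int(candidates[np.argmax(gaps[candidates])])
    if gaps[i] < min_prominence * mean_gap:
        return float("inf")
    return float((vals[i] + vals[i + 1]) / 2.0)


def refine_eqtl_set(
    pairs: list[EQTLPair], d: pd.Series, cutoff: float
) -> tuple[list[EQTLPair], list[EQTLPair]]:
    """Split the set into retained (d_i <= cutoff) and removed pairs.

    Pairs with missing d are dropped too (no usable well-matched data).
    Discrepancies are recorded on the pairs.
    """
    retained, removed = [], []
    for p in pairs:
        di = d.get(p.key, np.nan)
        p.discrepancy = None if np.isnan(di) else float(di)
        if np.isnan(di) or di > cutoff:
            removed.append(p)
        else:
            retained.append(p)
    if not retained:
        raise ValueError("refinement removed every eQTL pair")
    return retained, removed


def rescore(
    predicted: pd.DataFrame, observed: pd.DataFrame, retained: list[EQTLPair]
) -> ScoreMatrix:
    """Scores over the retained eQTL subset.

    Algebraically this subtracts the removed pairs' terms from the per-cell
    sums; it is computed by re-summing over the retained column index of
    the stored matrices, which is numerically identical to a from-scratch
    recomputation (and as cheap, vectorised).
    """
    keys = [p.key for p in retained]
    return score_matrix(predicted.loc[:, keys], observed.loc[keys])


# ---------------------------------------------------------------------------
# duplicate genotype arrays


def find_duplicate_genotype_arrays(
    geno: GenotypeMatrix, min_concordance: float = 0.995, min_overlap: int = 10
) -> list[list[str]]:
    """Groups of genotype arrays with (near-)identical calls.

    Duplicates are easy to find on the genotype side and are collapsed
    before ranking so the search maps onto a set of unique arrays.
    """
    vals = geno.values.to_numpy(dtype=float)
    ids = geno.array_ids
    n = len(ids)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = vals[:, i], vals[:, j]
            ok = ~np.isnan(a) & ~np.isnan(b)
            if ok.sum() < min_overlap:
                continue
            if (a[ok] == b[ok]).mean() >= min_concordance:
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(ids[i])
    return [g for g in groups.values() if len(g) > 1]


# ---------------------------------------------------------------------------
# the iteration loop


@dataclass
class BadgerConfig:
    """Tunable parameters of the iterative loop.

    ``trusted_samples``: samples whose intended mapping is known-good (an
    internal pilot); densities and, when scanning internally, the eQTL set
    are derived from them.  Without a pilot, all currently intended
    matches serve as training data.
    """

    window_bp: int = 1_000_000
    log10p_threshold: float = 15.0
    g: int = 1
    rank_threshold: int = 3
    accept_delta_percentile: float = 99.0
    orphan_percentile: float = 99.0
    refine: bool = True
    discrepancy_cutoff: float | None = None  # None = automatic histogram gap
    min_class_count: int = 3
    bandwidth_floor: float = 0.05
    max_iterations: int = 15
    max_cycle_length: int = 8
    collapse_duplicates: bool = True
    default_platform: str = "genotype"
    trusted_samples: tuple[str, ...] | None = None


@dataclass
class IterationLog:
    index: int
    n_eqtls: int
    n_eqtls_retained: int
    n_unresolved: int
    n_proposed: int
    n_accepted: int
    productive: bool
    accepted_kinds: list[str] = field(default_factory=list)


@dataclass
class BadgerResult:
    final_map: SampleMap
    report: MixupReport
    iterations: list[IterationLog]
    converged: bool
    scores: ScoreMatrix | None = None
    ranks: RankMatrix | None = None
    deltas: dict[str, DeltaStat] = field(default_factory=dict)


def _training_map(
    smap: SampleMap, config: BadgerConfig, confirmed: set[str] | None = None
) -> SampleMap:
    """Records whose intended mapping is currently trusted.

    Before any scoring has happened, trust is the configured pilot (or,
    without one, every intended match).  Afterwards, trust grows to the
    pilot plus all samples confirmed as reciprocal rank-1 matches in the
    previous iteration, so densities sharpen as the map is cleaned up.
    """
    if confirmed is None:
        if config.trusted_samples is None:
            return smap
        trusted = set(config.trusted_samples)
    else:
        trusted = set(config.trusted_samples or ()) | confirmed
    return SampleMap([r for r in smap.records if r.sample_id in trusted])


def run_badger(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    smap: SampleMap,
    eqtl_pairs: list[EQTLPair] | None = None,
    config: BadgerConfig | None = None,
) -> BadgerResult:
    """Iteratively score, propose, and apply corrections until stable.

    Each iteration refits the per-genotype densities on the training map
    (the full eQTL set is reinstated first), predicts and scores every
    expression/genotype array combination, refines the eQTL set by its
    discrepancy statistic, proposes corrections from the score/rank
    evidence, and applies those meeting the automatic acceptance policy.
    The loop ends with a confirming iteration that proposes no accepted
    changes, or stops early if a correction set recurs (oscillation guard).
    """
    from . import resolve  # local import: resolve is a sibling layer

    config = config or BadgerConfig()
    current = smap.copy()
    if eqtl_pairs is None:
        eqtl_pairs = scan_cis_associations(
            expr,
            geno,
            _training_map(current, config),
            window_bp=config.window_bp,
            log10p_threshold=config.log10p_threshold,
        )
        if not eqtl_pairs:
            raise ValueError("internal cis scan found no eQTL pairs")

    report = MixupReport()
    iterations: list[IterationLog] = []
    seen_signatures: set[frozenset] = set()
    converged = False
    scores = ranks = None
    deltas: dict[str, DeltaStat] = {}

    sample_of_e = smap.sample_of_expression()
    sample_of_g0 = smap.sample_of_genotype()
    for a in expr.array_ids:
        if expr.values[a].isna().all():
            report.corrections.append(
                Correction("empty", [], platform="expression",
                           evidence={"array": a, "intended_sample": sample_of_e.get(a)})
            )
    for a in geno.array_ids:
        if geno.values[a].isna().all():
            report.corrections.append(
                Correction("empty", [], platform="genotype",
                           evidence={"array": a, "intended_sample": sample_of_g0.get(a)})
            )

    dup_groups = (
        find_duplicate_genotype_arrays(geno) if config.collapse_duplicates else []
    )
    collapsed: set[str] = set()
    sample_of_g = smap.sample_of_genotype()
    for group in dup_groups:
        keep = group[0]
        collapsed.update(group[1:])
        report.corrections.append(
            Correction(
                "duplicate",
                [],
                platform="genotype",
                evidence={
                    "arrays": group,
                    "kept": keep,
                    "intended_samples": [sample_of_g.get(a) for a in group],
                },
            )
        )

    confirmed: set[str] | None = None
    for it in range(1, config.max_iterations + 1):
        # 1) reinstate the full set and refit densities on the training map
        training = _training_map(current, config, confirmed)
        training_basis = frozenset(s for s, _e, _g in training.matched_pairs())
        pairs = fit_eqtl_set(
            list(eqtl_pairs),
            expr,
            geno,
            training,
            min_class_count=config.min_class_count,
            bandwidth_floor=config.bandwidth_floor,
        )
        if not pairs:
            raise ValueError("no usable eQTL pair after density fitting")

        # 2) predict / observe / score / rank
        P = predict_matrix(pairs, expr)
        geno_use = geno.values.columns.difference(collapsed, sort=False)
        O = observed_matrix(pairs, geno).loc[:, geno_use]
        scores = score_matrix(P, O)
        ranks = rank_matrix(scores)

        # 3) refinement on currently well-matched pairs
        n_retained = len(pairs)
        if config.refine:
            well_matched = resolve.reciprocal_rank1_pairs(scores, ranks, current)
            if well_matched:
                d = eqtl_discrepancy(P, O, well_matched)
                cutoff = (
                    config.discrepancy_cutoff
                    if config.discrepancy_cutoff is not None
                    else auto_discrepancy_cutoff(d)
                )
                if np.isfinite(cutoff):
                    retained, _removed = refine_eqtl_set(pairs, d, cutoff)
                    if len(retained) < len(pairs):
                        scores = rescore(P, O, retained)
                        ranks = rank_matrix(scores)
                        n_retained = len(retained)

        deltas = delta_statistics(scores, g=config.g)
        sample_of_e = current.sample_of_expression()
        confirmed = {
            sample_of_e[e]
            for e, _g in resolve.reciprocal_rank1_pairs(scores, ranks, current)
            if e in sample_of_e
        }

        # 4) propose and vet corrections
        proposals = resolve.propose_corrections(
            current,
            scores,
            ranks,
            deltas,
            rank_threshold=config.rank_threshold,
            orphan_percentile=config.orphan_percentile,
            max_cycle_length=config.max_cycle_length,
        )
        accepted = resolve.vet_corrections(
            proposals,
            current,
            scores,
            ranks,
            deltas,
            accept_delta_percentile=config.accept_delta_percentile,
            default_platform=config.default_platform,
        )
        log = IterationLog(
            index=it,
            n_eqtls=len(pairs),
            n_eqtls_retained=n_retained,
            n_unresolved=len(resolve.unresolved_expression_arrays(ranks, current)),
            n_proposed=len(proposals),
            n_accepted=len(accepted),
            productive=bool(accepted),
            accepted_kinds=[c.kind for c in accepted],
        )
        iterations.append(log)
        logger.info(
            "iteration %d: %d eQTLs (%d after refinement), %d unresolved, "
            "%d proposed, %d accepted",
            it, log.n_eqtls, log.n_eqtls_retained, log.n_unresolved,
            log.n_proposed, log.n_accepted,
        )

        if not accepted:
            # nothing confidently correctable under the current densities;
            # if the trusted training set changed, refit and try once more
            # before declaring the state final
            next_basis = frozenset(set(config.trusted_samples or ()) | confirmed)
            if log.n_unresolved > 0 and next_basis != training_basis:
                continue
            converged = True
            for prop in proposals:
                report.unresolved.append(
                    {"kind": prop.kind, "moves": [m.__dict__ for m in prop.moves],
                     "evidence": prop.evidence}
                )
            break

        sig = frozenset(
            (c.kind, tuple(sorted((m.sample_id, m.expression_array, m.genotype_array)
                                  for m in c.moves)))
            for c in accepted
        )
        if sig in seen_signatures:
            report.notes.append("oscillation detected: identical correction set recurred")
            for prop in accepted:
                report.unresolved.append(
                    {"kind": prop.kind, "moves": [m.__dict__ for m in prop.moves]}
                )
            break
        seen_signatures.add(sig)

        current = apply_corrections(current, accepted)
        report.corrections.extend(accepted)

    return BadgerResult(
        final_map=current,
        report=report,
        iterations=iterations,
        converged=converged,
        scores=scores,
        ranks=ranks,
        deltas=deltas,
    )
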