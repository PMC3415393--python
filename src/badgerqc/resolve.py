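"""Turning score/rank evidence into concrete, attributed plating-error
hypotheses.

Unresolved arrays (those whose intended partner is not rank 1) are placed
on a bipartite graph with an edge wherever a rank is small; swaps appear as
short cycles alternating intended and evidence edges, larger rearrangements
as longer cycles or chains, and sequence slippage as a chain anchored by a
high-min-score orphan expression array at one end and an unclaimed (alien)
genotype array at the other.  Where full plate provenance is available,
systematic errors (wrong plate, 180-degree rotation, row/column reversal,
BeadChip strip reversal, +-1 sequence slippage) are tested wholesale and
reported when they strictly increase the number of rank-1 intended
matches.

Each correction is attributed to the platform on which the affected
samples were processing-neighbours at some stage; when they were
neighbours on both (or neither) the source cannot be identified and the
attribution is "undetermined".
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from .core import (
    Correction,
    DeltaStat,
    Move,
    PlateLayout,
    RankMatrix,
    SampleMap,
    ScoreMatrix,
    well_to_rc,
)

STAGE_EXTRACTION = "extraction"  # shared pre-split stage name convention


# ---------------------------------------------------------------------------
# bookkeeping helpers


def _expr_of(smap: SampleMap) -> dict[str, str]:
    return {r.sample_id: r.expression_array for r in smap.records if r.expression_array}


def _geno_of(smap: SampleMap) -> dict[str, str]:
    return {r.sample_id: r.genotype_array for r in smap.records if r.genotype_array}


def _extraction_positions(smap: SampleMap) -> tuple[dict[str, int], dict[int, str]]:
    pos_of, sample_at = {}, {}
    for r in smap.records:
        for p in r.provenance:
            if p.stage == STAGE_EXTRACTION and p.position is not None:
                pos_of[r.sample_id] = p.position
                sample_at[p.position] = r.sample_id
    return pos_of, sample_at


def _stage_entries(smap: SampleMap, platform: str):
    """[(sample, array, stage, plate, well, position)] for one platform."""
    out = []
    for r in smap.records:
        arr = r.genotype_array if platform == "genotype" else r.expression_array
        if not arr:
            continue
        for p in r.provenance:
            if p.platform == platform:
                out.append((r.sample_id, arr, p.stage, p.plate_id, p.well, p.position))
    return out


def _adjacent_on_platform(smap: SampleMap, s1: str, s2: str, platform: str) -> bool:
    """True if the two samples were processing-neighbours on the platform:
    adjacent positions in a stage sequence, or orthogonally adjacent wells
    of the same plate."""
    loc1 = {e[2]: e for e in _stage_entries(smap, platform) if e[0] == s1}
    loc2 = {e[2]: e for e in _stage_entries(smap, platform) if e[0] == s2}
    for stage in set(loc1) & set(loc2):
        _, _, _, pl1, w1, p1 = loc1[stage]
        _, _, _, pl2, w2, p2 = loc2[stage]
        if p1 is not None and p2 is not None and abs(p1 - p2) == 1:
            return True
        if pl1 == pl2:
            (r1, c1), (r2, c2) = well_to_rc(w1), well_to_rc(w2)
            if abs(r1 - r2) + abs(c1 - c2) == 1:
                return True
    return False


def attribute_platform(smap: SampleMap, samples: list[str]) -> str:
    """Platform attribution for a set of co-affected samples."""
    pairs = list(itertools.combinations(set(samples), 2))
    expr_adj = any(_adjacent_on_platform(smap, a, b, "expression") for a, b in pairs)
    geno_adj = any(_adjacent_on_platform(smap, a, b, "genotype") for a, b in pairs)
    if geno_adj and not expr_adj:
        return "genotype"
    if expr_adj and not geno_adj:
        return "expression"
    return "undetermined"


# ---------------------------------------------------------------------------
# resolved / unresolved status


def column_best(scores: ScoreMatrix) -> dict[str, str | None]:
    """Best-scoring expression array per genotype column (None if the
    column is entirely missing)."""
    vals = scores.scores.to_numpy(dtype=float)
    out: dict[str, str | None] = {}
    for j, ga in enumerate(scores.genotype_ids):
        col = vals[:, j]
        ok = ~np.isnan(col)
        out[ga] = scores.expression_ids[int(np.flatnonzero(ok)[col[ok].argmin()])] if ok.any() else None
    return out


def reciprocal_rank1_pairs(
    scores: ScoreMatrix, ranks: RankMatrix, smap: SampleMap
) -> list[tuple[str, str]]:
    """Intended pairs where the genotype array is rank 1 for its expression
    array and that expression array is the best row for the column."""
    col_best = column_best(scores)
    out = []
    for _, e, g in smap.matched_pairs():
        if e not in ranks.ranks.index or g not in ranks.ranks.columns:
            continue
        r = ranks.ranks.loc[e, g]
        if not np.isnan(r) and int(r) == 1 and col_best.get(g) == e:
            out.append((e, g))
    return out


def matched_min_scores(scores: ScoreMatrix, ranks: RankMatrix, smap: SampleMap) -> np.ndarray:
    pairs = reciprocal_rank1_pairs(scores, ranks, smap)
    return np.array([scores.scores.loc[e, g] for e, g in pairs], dtype=float)


def unresolved_expression_arrays(ranks: RankMatrix, smap: SampleMap) -> list[str]:
    """Expression arrays whose intended genotype partner is not rank 1.

    Arrays without scores (empty arrays) and arrays whose partner is not in
    the ranked columns (e.g. collapsed duplicates) are skipped: they are
    reported through other channels."""
    out = []
    rk = ranks.ranks
    for _, e, g in smap.matched_pairs():
        if e not in rk.index or g not in rk.columns:
            continue
        row = rk.loc[e]
        if row.isna().all():
            continue
        r = row[g]
        if np.isnan(r) or int(r) != 1:
            out.append(e)
    return out


def unresolved_genotype_arrays(
    scores: ScoreMatrix, smap: SampleMap, ranks: RankMatrix | None = None
) -> list[str]:
    """Genotype arrays whose intended expression array does not rank them
    first."""
    rk = ranks.ranks if ranks is not None else None
    out = []
    for _, e, g in smap.matched_pairs():
        if g not in scores.scores.columns:
            continue
        if rk is not None and e in rk.index:
            r = rk.loc[e, g]
            if np.isnan(r) or int(r) != 1:
                out.append(g)
        elif rk is None and column_best(scores).get(g) != e:
            out.append(g)
    return out


# ---------------------------------------------------------------------------
# the mismatch graph


def build_mismatch_graph(
    scores: ScoreMatrix,
    ranks: RankMatrix,
    smap: SampleMap,
    deltas: dict[str, DeltaStat] | None = None,
    rank_threshold: int = 3,
    orphan_percentile: float = 99.0,
) -> nx.Graph:
    """Bipartite graph of unresolved arrays.

    Nodes are ("E", array) / ("G", array) with sample, min-score and orphan
    attributes; an evidence edge joins (e, g) when BR_eg < rank_threshold,
    and intended-mapping edges are marked ``intended=True``.
    """
    g = nx.Graph()
    unresolved_e = unresolved_expression_arrays(ranks, smap)
    unresolved_g = unresolved_genotype_arrays(scores, smap, ranks)
    if not unresolved_e and not unresolved_g:
        return g

    matched = matched_min_scores(scores, ranks, smap)
    # an orphan/alien array matches nothing, so its best score sits at the
    # level of random non-matching pairs (the score bulk), far above both
    # the matched distribution and any merely mis-mapped array
    all_scores = scores.scores.to_numpy(dtype=float)
    bulk = float(np.nanmedian(all_scores)) if np.isfinite(all_scores).any() else float("inf")
    orphan_thr = (
        max(float(np.percentile(matched, orphan_percentile)), 0.25 * bulk)
        if len(matched)
        else float("inf")
    )
    sample_of_e = smap.sample_of_expression()
    sample_of_g = smap.sample_of_genotype()
    geno_of = _geno_of(smap)

    # a true orphan/alien shows no reciprocal structure: its best match is
    # somebody else's reciprocal partner, not its own
    col_of_best = column_best(scores)
    for e in unresolved_e:
        row = scores.scores.loc[e]
        has = row.notna().any()
        mn = float(row.min()) if has else float("nan")
        reciprocal = has and col_of_best.get(row.idxmin()) == e
        g.add_node(
            ("E", e),
            bipartite=0,
            sample=sample_of_e.get(e),
            min_score=mn,
            orphan=bool(has and mn > orphan_thr and not reciprocal),
        )
    for ga in unresolved_g:
        col = scores.scores[ga]
        has = col.notna().any()
        mn = float(col.min()) if has else float("nan")
        if has:
            e_best = col_of_best.get(ga)
            r = ranks.ranks.loc[e_best, ga] if e_best is not None else np.nan
            reciprocal = not np.isnan(r) and int(r) == 1
        else:
            reciprocal = False
        g.add_node(
            ("G", ga),
            bipartite=1,
            sample=sample_of_g.get(ga),
            min_score=mn,
            alien=bool(has and mn > orphan_thr and not reciprocal),
        )

    for e in unresolved_e:
        row = ranks.ranks.loc[e]
        for ga, r in row.items():
            if np.isnan(r) or r >= rank_threshold:
                continue
            if ("G", ga) not in g:
                g.add_node(
                    ("G", ga),
                    bipartite=1,
                    sample=sample_of_g.get(ga),
                    min_score=float(scores.scores[ga].min()),
                    alien=False,
                )
            g.add_edge(
                ("E", e), ("G", ga),
                rank=int(r), score=float(scores.scores.loc[e, ga]), intended=False,
            )
    for s, e, ga in smap.matched_pairs():
        if ("E", e) in g:
            if ("G", ga) not in g:
                g.add_node(("G", ga), bipartite=1, sample=s,
                           min_score=float(scores.scores[ga].min())
                           if ga in scores.scores.columns else float("nan"),
                           alien=False)
            if g.has_edge(("E", e), ("G", ga)):
                g[("E", e)][("G", ga)]["intended"] = True
            else:
                g.add_edge(("E", e), ("G", ga), rank=None, score=None, intended=True)
    g.graph["orphan_threshold"] = orphan_thr
    g.graph["geno_of"] = geno_of
    return g


def graph_to_dot(g: nx.Graph) -> str:
    """DOT export for eyeballing the mismatch structure."""
    lines = ["graph mismatches {"]
    for node, data in g.nodes(data=True):
        side, arr = node
        shape = "ellipse" if side == "E" else "box"
        extra = " (orphan)" if data.get("orphan") else (" (alien)" if data.get("alien") else "")
        lines.append(
            f'  "{side}:{arr}" [shape={shape} label="{arr}\\n{data.get("sample")}{extra}"];'
        )
    for a, b, data in g.edges(data=True):
        style = "dashed" if data.get("intended") else "solid"
        label = "" if data.get("rank") is None else f', label="{data["rank"]}"'
        lines.append(f'  "{a[0]}:{a[1]}" -- "{b[0]}:{b[1]}" [style={style}{label}];')
    lines.append("}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# cycles and chains


def _psi_mapping(g: nx.Graph, ranks: RankMatrix, smap: SampleMap) -> dict[str, str]:
    """sample -> sample mapping: psi(s) is the intended owner of the
    genotype array that best matches s's expression array (rank 1)."""
    psi = {}
    sample_of_g = smap.sample_of_genotype()
    for node, data in g.nodes(data=True):
        if node[0] != "E" or data.get("orphan"):
            continue
        e = node[1]
        row = ranks.ranks.loc[e]
        best = row[row == 1]
        if best.empty:
            continue
        ga = best.index[0]
        tgt = sample_of_g.get(ga)
        psi[data["sample"]] = tgt if tgt is not None else f"?array:{ga}"
    return psi


def find_cycles_and_chains(
    g: nx.Graph,
    smap: SampleMap,
    ranks: RankMatrix,
    max_cycle_length: int = 8,
) -> list[Correction]:
    """Enumerate cyclic relabelings and slippage/chain hypotheses.

    Cycles are read off the functional graph psi; chains must end at an
    orphan expression array and start at a sample whose own genotype array
    is claimed by nobody (typically holding an alien).  When every chain
    step is consistent with a one-position shift of the pre-exclusion
    extraction sequence, the hypothesis is emitted as slippage and the
    alien occupant is named from the sequence.  Cycle corrections whose
    samples form a contiguous block reversal of a stage sequence are merged
    into a single correction so the entire error is identified, not just a
    part of it.
    """
    if g.number_of_nodes() == 0:
        return []
    psi = _psi_mapping(g, ranks, smap)
    expr_of, geno_of = _expr_of(smap), _geno_of(smap)
    pos_of, sample_at = _extraction_positions(smap)

    dg = nx.DiGraph()
    for s, t in psi.items():
        if not t.startswith("?array:"):
            dg.add_edge(s, t)

    corrections: list[Correction] = []
    used: set[str] = set()

    # ---- cycles
    for cyc in nx.simple_cycles(dg):
        if len(cyc) > max_cycle_length:
            corrections.append(
                Correction(
                    "cycle",
                    [],
                    evidence={"cycle_samples": list(cyc), "too_long": True},
                )
            )
            used.update(cyc)
            continue
        moves = [Move(s, expr_of.get(s), geno_of.get(psi[s])) for s in cyc]
        corrections.append(
            Correction(
                "swap" if len(cyc) == 2 else "cycle",
                moves,
                evidence={"cycle_samples": list(cyc)},
            )
        )
        used.update(cyc)

    # ---- chains ending at orphans
    orphans = {
        data["sample"] for node, data in g.nodes(data=True)
        if node[0] == "E" and data.get("orphan")
    }
    in_image = set(psi.values())
    starts = [s for s in psi if s not in in_image and s not in used]
    for s0 in starts:
        chain = [s0]
        cur = s0
        while cur in psi and not psi[cur].startswith("?array:"):
            nxt = psi[cur]
            if nxt in chain or nxt in used:
                break
            chain.append(nxt)
            cur = nxt
        if len(chain) < 2 or chain[-1] not in orphans:
            continue
        used.update(chain)
        moves = [
            Move(s, expr_of.get(s), geno_of.get(psi[s])) for s in chain[:-1]
        ]
        moves.append(Move(chain[-1], expr_of.get(chain[-1]), None))

        # sequence-consistency: every step shifts one extraction position
        steps_ok = all(
            pos_of.get(chain[i]) is not None
            and pos_of.get(chain[i + 1]) is not None
            and pos_of[chain[i]] - pos_of[chain[i + 1]] == 1
            for i in range(len(chain) - 1)
        )
        kind = "chain"
        evidence = {"chain_samples": list(chain)}
        if steps_ok and pos_of.get(chain[0]) is not None:
            alien_pos = pos_of[chain[0]] + 1
            alien = sample_at.get(alien_pos)
            kind = "slippage"
            evidence["shift"] = +1
            if alien is not None and alien not in expr_of and alien not in geno_of:
                moves.append(Move(alien, None, geno_of.get(chain[0])))
                evidence["alien"] = alien
        corrections.append(Correction(kind, moves, evidence=evidence))

    return _merge_block_reversals(corrections, smap)


def _merge_block_reversals(corrections: list[Correction], smap: SampleMap) -> list[Correction]:
    """Merge 2-cycles that together reverse a contiguous even-length block
    of one platform's stage sequence into a single correction (so the
    entire error is identified, not just its middle)."""
    swaps = [c for c in corrections if c.kind == "swap" and c.moves]
    if len(swaps) < 2:
        return corrections
    others = [c for c in corrections if c not in swaps]

    for platform in ("genotype", "expression"):
        pos = {}
        for s, _a, _st, _pl, _w, p in _stage_entries(smap, platform):
            if p is not None:
                pos[s] = p
        # a reversal of block [a, b] is the set of swaps (a+i, b-i): all
        # position pairs share the sum a+b and the low ends are consecutive
        by_sum: dict[int, list[tuple[int, Correction]]] = {}
        for c in swaps:
            ps = sorted(pos.get(s, -1) for s in c.affected_samples())
            if len(ps) != 2 or -1 in ps:
                continue
            by_sum.setdefault(ps[0] + ps[1], []).append((ps[0], c))
        merged: list[Correction] = []
        consumed: set[int] = set()
        for total, group in by_sum.items():
            group.sort()
            run: list[tuple[int, Correction]] = []
            for lo, c in group + [(-(10**9), None)]:
                if run and lo != run[-1][0] + 1:
                    if len(run) >= 2 and run[-1][0] + 1 == total - run[-1][0]:
                        # nested pairs cover [run[0].lo, total - run[0].lo]
                        moves = [m for _lo, cc in run for m in cc.moves]
                        merged.append(
                            Correction(
                                "cycle",
                                moves,
                                evidence={
                                    "transform": "block_reversal",
                                    "platform_hint": platform,
                                    "positions": [run[0][0], total - run[0][0]],
                                },
                            )
                        )
                        consumed.update(id(cc) for _lo, cc in run)
                    run = []
                if c is not None:
                    run.append((lo, c))
        if merged:
            swaps = [c for c in swaps if id(c) not in consumed]
            others.extend(merged)
    return others + swaps


# ---------------------------------------------------------------------------
# systematic plate transforms


def _stage_plates(smap: SampleMap, platform: str) -> dict[tuple[str, str], PlateLayout]:
    plates: dict[tuple[str, str], PlateLayout] = {}
    for s, _arr, stage, plate, well, _pos in _stage_entries(smap, platform):
        lay = plates.setdefault((stage, plate), PlateLayout.empty(plate))
        lay.set_well(well, s)
    return plates


def _hypothesis_correction(
    hypo: dict[str, str],
    platform: str,
    smap: SampleMap,
    scores: ScoreMatrix,
    ranks: RankMatrix,
    name: str,
    detail: dict,
) -> Correction | None:
    """Score a wholesale re-assignment hypothesis {array: new_sample}.

    Emitted only when it strictly increases the number of rank-1 intended
    matches over the affected arrays.
    """
    expr_of, geno_of = _expr_of(smap), _geno_of(smap)
    sample_of = smap.sample_of_genotype() if platform == "genotype" else smap.sample_of_expression()
    rk = ranks.ranks

    def pair_rank(e, ga):
        if e is None or ga is None or e not in rk.index or ga not in rk.columns:
            return np.nan
        return rk.loc[e, ga]

    gain_new = gain_old = 0
    all_new_ok = True
    moves = []
    placed = set()
    for arr, new_s in hypo.items():
        old_s = sample_of.get(arr)
        if new_s == old_s:
            continue
        if platform == "genotype":
            new_r = pair_rank(expr_of.get(new_s), arr)
            old_r = pair_rank(expr_of.get(old_s), arr)
            moves.append(Move(new_s, expr_of.get(new_s), arr))
        else:
            new_r = pair_rank(arr, geno_of.get(new_s))
            old_r = pair_rank(arr, geno_of.get(old_s))
            moves.append(Move(new_s, arr, geno_of.get(new_s)))
        placed.add(new_s)
        gain_new += int(new_r == 1)
        gain_old += int(old_r == 1)
        if not np.isnan(new_r) and new_r != 1:
            all_new_ok = False
    displaced = {sample_of.get(a) for a in hypo} - placed - {None}
    for s in displaced:
        moves.append(
            Move(s, expr_of.get(s), None) if platform == "genotype"
            else Move(s, None, geno_of.get(s))
        )
    if not moves or gain_new <= gain_old:
        return None
    return Correction(
        "plate_transform",
        moves,
        platform=platform,
        evidence={
            "transform": name,
            "gain": gain_new - gain_old,
            "rank1_under_hypothesis": gain_new,
            "rank1_as_intended": gain_old,
            "all_repaired_rank1": all_new_ok,
            **detail,
        },
    )


def enumerate_plate_transforms(
    smap: SampleMap,
    scores: ScoreMatrix,
    ranks: RankMatrix,
    platforms: tuple[str, ...] = ("genotype", "expression"),
) -> list[Correction]:
    """Test systematic plating errors stage by stage.

    Per plate: 180-degree rotation, row-order reversal, column-order
    reversal (for a 12-well expression strip this is the BeadChip strip
    reversal); across plates of equal occupancy: plate swaps; per stage
    sequence: +-1 slippage.  Any transform strictly increasing the number
    of rank-1 intended matches is reported with the count gained.
    """
    out: list[Correction] = []
    for platform in platforms:
        entries = _stage_entries(smap, platform)
        if not entries:
            continue
        arr_of = {s: a for s, a, *_ in entries}
        plates = _stage_plates(smap, platform)

        for (stage, pid), lay in sorted(plates.items()):
            occ = set(lay.occupied_wells())
            for name, tlay in (
                ("rotation_180", lay.rotate180()),
                ("row_reversal", lay.reverse_rows()),
                ("column_reversal", lay.reverse_columns()),
            ):
                if set(tlay.occupied_wells()) != occ:
                    continue
                hypo = {
                    arr_of[lay.sample_at(w)]: tlay.sample_at(w)
                    for w in occ
                    if tlay.sample_at(w) != lay.sample_at(w)
                }
                corr = _hypothesis_correction(
                    hypo, platform, smap, scores, ranks, name,
                    {"stage": stage, "plate": pid},
                )
                if corr:
                    out.append(corr)

        for (st_a, pa), (st_b, pb) in itertools.combinations(sorted(plates), 2):
            if st_a != st_b:
                continue
            la, lb = plates[(st_a, pa)], plates[(st_b, pb)]
            if set(la.occupied_wells()) != set(lb.occupied_wells()):
                continue
            hypo = {}
            for w in la.occupied_wells():
                hypo[arr_of[la.sample_at(w)]] = lb.sample_at(w)
                hypo[arr_of[lb.sample_at(w)]] = la.sample_at(w)
            corr = _hypothesis_correction(
                hypo, platform, smap, scores, ranks, "plate_swap",
                {"stage": st_a, "plates": [pa, pb]},
            )
            if corr:
                out.append(corr)

        # global +-1 slippage over the stage sequence
        seq = sorted(
            [(p, s, a) for s, a, _st, _pl, _w, p in entries if p is not None]
        )
        if len(seq) >= 3:
            order_s = [s for _p, s, _a in seq]
            order_a = [a for _p, _s, a in seq]
            for shift in (+1, -1):
                hypo = {}
                for i, arr in enumerate(order_a):
                    j = i + shift
                    if 0 <= j < len(order_s):
                        hypo[arr] = order_s[j]
                corr = _hypothesis_correction(
                    hypo, platform, smap, scores, ranks, "sequence_slippage",
                    {"shift": shift},
                )
                if corr:
                    out.append(corr)
    out.sort(key=lambda c: -c.evidence.get("gain", 0))
    return out


# ---------------------------------------------------------------------------
# orchestration: propose, attribute, vet, apply


def propose_corrections(
    smap: SampleMap,
    scores: ScoreMatrix,
    ranks: RankMatrix,
    deltas: dict[str, DeltaStat],
    rank_threshold: int = 3,
    orphan_percentile: float = 99.0,
    max_cycle_length: int = 8,
) -> list[Correction]:
    """All candidate corrections, transforms first (a systematic error
    should be identified whole, not as a pile of pairwise swaps)."""
    graph = build_mismatch_graph(
        scores, ranks, smap, deltas,
        rank_threshold=rank_threshold, orphan_percentile=orphan_percentile,
    )
    if graph.number_of_nodes() == 0:
        return []
    transforms = enumerate_plate_transforms(smap, scores, ranks)
    cycles = find_cycles_and_chains(graph, smap, ranks, max_cycle_length)
    orphan_thr = graph.graph.get("orphan_threshold", float("inf"))

    proposals = transforms + cycles

    # alien genotype arrays not explained by any chain: flag, unpair
    claimed = {
        m.genotype_array for c in proposals for m in c.moves if m.genotype_array
    }
    for node, data in graph.nodes(data=True):
        if node[0] == "G" and data.get("alien") and node[1] not in claimed:
            s = data.get("sample")
            if s is None:
                continue
            expr_of = _expr_of(smap)
            proposals.append(
                Correction(
                    "alien",
                    [Move(s, expr_of.get(s), None)],
                    evidence={"array": node[1], "column_min_score": data.get("min_score")},
                )
            )
    # orphan expression arrays not covered elsewhere: report-only
    covered = {m.sample_id for c in proposals for m in c.moves}
    for node, data in graph.nodes(data=True):
        if node[0] == "E" and data.get("orphan") and data.get("sample") not in covered:
            proposals.append(
                Correction(
                    "orphan",
                    [],
                    evidence={"array": node[1], "sample": data.get("sample"),
                              "min_score": data.get("min_score")},
                )
            )
    return proposals


def _rebuild_moves_for_expression(corr: Correction, smap: SampleMap) -> list[Move]:
    """Reinterpret a cycle found on the psi graph as an expression-side
    relabeling: psi(s) = t means s's expression array actually carries t's
    RNA, so t should own that expression array."""
    cyc = corr.evidence.get("cycle_samples")
    if not cyc:
        return corr.moves
    expr_of, geno_of = _expr_of(smap), _geno_of(smap)
    moves = []
    for i, s in enumerate(cyc):
        t = cyc[(i + 1) % len(cyc)]
        moves.append(Move(t, expr_of.get(s), geno_of.get(t)))
    return moves


def attribute_corrections(
    corrections: list[Correction],
    smap: SampleMap,
    default_platform: str = "genotype",
) -> list[Correction]:
    """Set each correction's platform and finalise its moves accordingly."""
    out = []
    for corr in corrections:
        c = Correction(corr.kind, list(corr.moves), corr.platform, dict(corr.evidence))
        if c.kind in ("swap", "cycle", "chain", "slippage") and c.moves:
            samples = sorted(c.affected_samples())
            platform = attribute_platform(smap, samples)
            c.platform = platform
            applied_as = platform if platform != "undetermined" else default_platform
            c.evidence["applied_as"] = applied_as
            if applied_as == "expression" and "cycle_samples" in c.evidence:
                c.moves = _rebuild_moves_for_expression(c, smap)
        out.append(c)
    return out


def vet_corrections(
    proposals: list[Correction],
    smap: SampleMap,
    scores: ScoreMatrix,
    ranks: RankMatrix,
    deltas: dict[str, DeltaStat],
    accept_delta_percentile: float = 99.0,
    default_platform: str = "genotype",
) -> list[Correction]:
    """Automatic acceptance policy for unattended runs.

    A relabeling is accepted only when every re-paired (expression,
    genotype) combination is reciprocal rank 1 under the current scores and
    the expression array's gap statistic exceeds the
    ``accept_delta_percentile``-th percentile of the matched-pair min
    scores (i.e. the margin the correction creates is larger than any
    score a genuinely matched array attains, so coincidence is ruled out
    on the cohort's own scale).  Plate transforms must gain at least one
    rank-1 intended match with every re-paired combination rank 1.
    Everything else is left for review.  Accepted corrections are disjoint
    (first come, first served in transform-gain order).
    """
    attributed = attribute_corrections(proposals, smap, default_platform)
    matched = matched_min_scores(scores, ranks, smap)
    delta_need = (
        float(np.percentile(matched, accept_delta_percentile)) if len(matched) else 0.0
    )
    col_best = column_best(scores)
    rk = ranks.ranks

    accepted: list[Correction] = []
    used_samples: set[str] = set()
    used_arrays: set[tuple[str, str]] = set()

    for corr in attributed:
        if not corr.moves:
            continue
        if corr.kind in ("alien", "orphan"):
            # un-pairing an array is destructive and rests only on absence
            # of a match; left for human review (and lab validation)
            continue
        if corr.affected_samples() & used_samples or corr.affected_arrays() & used_arrays:
            continue
        ok = True
        for mv in corr.moves:
            e, ga = mv.expression_array, mv.genotype_array
            if e and ga:
                if e not in rk.index or ga not in rk.columns:
                    ok = False
                    break
                r = rk.loc[e, ga]
                if np.isnan(r) or int(r) != 1 or col_best.get(ga) != e:
                    ok = False
                    break
                if corr.kind in ("swap", "cycle", "chain", "slippage"):
                    d = deltas.get(e)
                    if d is None or not (d.gap > 0 and d.gap > delta_need):
                        ok = False
                        break
        if ok and corr.kind == "plate_transform":
            ok = corr.evidence.get("gain", 0) >= 1 and corr.evidence.get(
                "all_repaired_rank1", False
            )
        if ok:
            accepted.append(corr)
            used_samples |= corr.affected_samples()
            used_arrays |= corr.affected_arrays()
    return accepted


def attribute_and_apply(
    corrections: list[Correction],
    smap: SampleMap,
    default_platform: str = "genotype",
):
    """Attribute, check disjointness, and apply a correction set.

    Overlapping corrections are a conflict: none is applied and the report
    says so (the caller should resolve priorities first).
    Returns (new map, MixupReport).
    """
    from .core import MixupReport, apply_corrections

    attributed = attribute_corrections(corrections, smap, default_platform)
    seen_s: set[str] = set()
    seen_a: set[tuple[str, str]] = set()
    for c in attributed:
        if c.affected_samples() & seen_s or c.affected_arrays() & seen_a:
            report = MixupReport(
                corrections=[],
                notes=["conflict: overlapping corrections; none applied"],
            )
            return smap.copy(), report
        seen_s |= c.affected_samples()
        seen_a |= c.affected_arrays()
    applicable = [c for c in attributed if c.moves]
    new_map = apply_corrections(smap, applicable)
    return new_map, MixupReport(corrections=attributed)
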