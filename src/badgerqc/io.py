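"""Readers and writers for the native text formats.

Matrices travel as TSV (first column = feature ID, header = array IDs) with
a TSV annotation sidecar; sample maps and plate layouts as CSV; eQTL sets
and mix-up reports as JSON.  Genotypes can additionally be imported from
VCF (GT field converted to B-allele counts; multi-allelic sites are
skipped with a logged warning).  All native round-trips are lossless.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    Correction,
    ExpressionMatrix,
    GenotypeMatrix,
    MixupReport,
    Move,
    PLATE_N_COLS,
    PLATE_N_ROWS,
    PlateLayout,
    ProvenanceEntry,
    SampleMap,
    SampleRecord,
)
from .eqtl import ClassDensity, EQTLPair

logger = logging.getLogger(__name__)

_NA = "NA"


class FormatError(ValueError):
    """Malformed input; the message carries the offending line number."""


# ---------------------------------------------------------------------------
# matrices


def _write_matrix(values: pd.DataFrame, path, feature_label: str) -> None:
    values.to_csv(path, sep="\t", index_label=feature_label, na_rep=_NA)


def _read_matrix(path, feature_label: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[_NA], keep_default_na=False)
    df.index.name = feature_label
    return df


def write_expression(expr: ExpressionMatrix, values_path, annotation_path) -> None:
    _write_matrix(expr.values, values_path, "probe_id")
    expr.probe_annotation.to_csv(annotation_path, sep="\t", index_label="probe_id")


def read_expression(values_path, annotation_path) -> ExpressionMatrix:
    values = _read_matrix(values_path, "probe_id")
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0, dtype={"chromosome": str})
    return ExpressionMatrix(values, ann)


def write_genotype(geno: GenotypeMatrix, values_path, annotation_path) -> None:
    # counts as integers where present, NA where missing
    out = geno.values.map(lambda v: _NA if pd.isna(v) else str(int(v)))
    out.to_csv(values_path, sep="\t", index_label="snp_id")
    geno.snp_annotation.to_csv(annotation_path, sep="\t", index_label="snp_id")


def read_genotype(values_path, annotation_path) -> GenotypeMatrix:
    values = _read_matrix(values_path, "snp_id").astype(float)
    bad = values.stack(future_stack=True).dropna()
    invalid = bad[~bad.isin((0.0, 1.0, 2.0))]
    if not invalid.empty:
        snp, arr = invalid.index[0]
        with open(values_path) as fh:
            for lineno, line in enumerate(fh, 1):
                if line.split("\t", 1)[0] == str(snp):
                    raise FormatError(
                        f"{values_path}:{lineno}: genotype value {invalid.iloc[0]!r} "
                        f"for {snp}/{arr} not in {{0,1,2,NA}}"
                    )
        raise FormatError(f"invalid genotype value {invalid.iloc[0]!r} for {snp}/{arr}")
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0, dtype={"chromosome": str})
    return GenotypeMatrix(values, ann)


def read_genotype_vcf(path) -> GenotypeMatrix:
    """Import genotypes from a VCF: GT 0/0, 0/1, 1/1 -> 0, 1, 2; ./. ->
    missing.  Multi-allelic sites are skipped with a warning."""
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    snp_ids, rows, chroms, positions = [], [], [], []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            logger.warning(
                "skipping multi-allelic site %s:%d (%s)", rec.chrom, rec.pos, rec.id
            )
            continue
        counts = []
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                counts.append(np.nan)
            else:
                counts.append(float(sum(1 for a in gt if a == 1)))
        snp_ids.append(rec.id if rec.id else f"{rec.chrom}:{rec.pos}")
        chroms.append(str(rec.chrom))
        positions.append(int(rec.pos))
        rows.append(counts)
    values = pd.DataFrame(rows, index=snp_ids, columns=samples)
    ann = pd.DataFrame({"chromosome": chroms, "position": positions}, index=snp_ids)
    return GenotypeMatrix(values, ann)


# ---------------------------------------------------------------------------
# sample map


def _provenance_to_str(prov) -> str:
    return "|".join(
        f"{p.stage}@{p.platform}:{p.plate_id}:{p.well}:{'' if p.position is None else p.position}"
        for p in prov
    )


def _provenance_from_str(s: str, lineno: int) -> tuple[ProvenanceEntry, ...]:
    if not s:
        return ()
    entries = []
    for tok in s.split("|"):
        try:
            stage_platform, plate, well, pos = tok.split(":")
            stage, platform = stage_platform.split("@")
        except ValueError as exc:
            raise FormatError(f"line {lineno}: malformed provenance token {tok!r}") from exc
        entries.append(
            ProvenanceEntry(stage, platform, plate, well, int(pos) if pos else None)
        )
    return tuple(entries)


def write_sample_map(smap: SampleMap, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "expression_array", "genotype_array", "tissue", "provenance"])
        for r in smap.records:
            w.writerow(
                [
                    r.sample_id,
                    r.expression_array or "",
                    r.genotype_array or "",
                    r.tissue,
                    _provenance_to_str(r.provenance),
                ]
            )


def read_sample_map(path) -> SampleMap:
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or header[:4] != ["sample_id", "expression_array", "genotype_array", "tissue"]:
            raise FormatError(f"{path}:1: unexpected sample-map header {header!r}")
        for lineno, row in enumerate(reader, 2):
            if not row:
                continue
            if len(row) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 fields, got {len(row)}")
            sid, ea, ga, tissue, prov = row
            records.append(
                SampleRecord(
                    sid, ea or None, ga or None, tissue, _provenance_from_str(prov, lineno)
                )
            )
    return SampleMap(records)


# ---------------------------------------------------------------------------
# plate layout


def write_plate_layout(layout: PlateLayout, path) -> None:
    """CSV grid: header = columns 1-12, first field = row letter, cells
    ``sample|sex`` (either part may be empty)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([layout.plate_id] + [str(c + 1) for c in range(PLATE_N_COLS)])
        for r in range(PLATE_N_ROWS):
            cells = []
            for c in range(PLATE_N_COLS):
                s = layout.samples[r, c] or ""
                x = layout.sexes[r, c] or ""
                cells.append(f"{s}|{x}" if (s or x) else "")
            w.writerow(["ABCDEFGH"[r]] + cells)


def read_plate_layout(path) -> PlateLayout:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or len(header) != PLATE_N_COLS + 1:
            raise FormatError(f"{path}:1: plate header must list 12 columns")
        layout = PlateLayout.empty(header[0])
        for lineno, row in enumerate(reader, 2):
            if len(row) != PLATE_N_COLS + 1:
                raise FormatError(f"{path}:{lineno}: expected 13 fields, got {len(row)}")
            try:
                r = "ABCDEFGH".index(row[0])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad row letter {row[0]!r}") from exc
            for c, cell in enumerate(row[1:]):
                if not cell:
                    continue
                sample, _, sex = cell.partition("|")
                layout.samples[r, c] = sample or None
                layout.sexes[r, c] = sex or None
    return layout


# ---------------------------------------------------------------------------
# eQTL sets


def write_eqtl_set(pairs: list[EQTLPair], path, grid_points: int = 128) -> None:
    """JSON with association stats, class counts and the exact density
    parameters (training points + bandwidth), plus an evaluation grid for
    external reproducibility."""
    payload = []
    for p in pairs:
        densities = {}
        for cls, d in p.densities.items():
            x, fx = d.grid(grid_points)
            densities[str(cls)] = {
                "points": [float(v) for v in d.points],
                "bandwidth": float(d.bandwidth),
                "grid_x": [round(float(v), 6) for v in x],
                "grid_f": [round(float(v), 6) for v in fx],
            }
        payload.append(
            {
                "probe_id": p.probe_id,
                "snp_id": p.snp_id,
                "association_log10p": p.association_log10p,
                "class_counts": {str(k): v for k, v in p.class_counts.items()},
                "discrepancy": p.discrepancy,
                "densities": densities,
            }
        )
    Path(path).write_text(json.dumps(payload, indent=1))


def read_eqtl_set(path) -> list[EQTLPair]:
    payload = json.loads(Path(path).read_text())
    pairs = []
    for item in payload:
        pair = EQTLPair(
            item["probe_id"],
            item["snp_id"],
            item["association_log10p"],
            discrepancy=item.get("discrepancy"),
        )
        pair.class_counts = {int(k): v for k, v in item.get("class_counts", {}).items()}
        pair.densities = {
            int(cls): ClassDensity(np.array(d["points"], dtype=float), d["bandwidth"])
            for cls, d in item.get("densities", {}).items()
        }
        pairs.append(pair)
    return pairs


# ---------------------------------------------------------------------------
# mix-up reports


def _correction_to_dict(c: Correction) -> dict:
    return {
        "kind": c.kind,
        "platform": c.platform,
        "moves": [
            {
                "sample_id": m.sample_id,
                "expression_array": m.expression_array,
                "genotype_array": m.genotype_array,
            }
            for m in c.moves
        ],
        "evidence": c.evidence,
    }


def write_mixup_report(report: MixupReport, path) -> None:
    payload = {
        "corrections": [_correction_to_dict(c) for c in report.corrections],
        "unresolved": report.unresolved,
        "notes": report.notes,
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=str))


def read_mixup_report(path) -> MixupReport:
    payload = json.loads(Path(path).read_text())
    corrections = [
        Correction(
            c["kind"],
            [
                Move(m["sample_id"], m["expression_array"], m["genotype_array"])
                for m in c["moves"]
            ],
            c.get("platform", "undetermined"),
            c.get("evidence", {}),
        )
        for c in payload.get("corrections", [])
    ]
    return MixupReport(corrections, payload.get("unresolved", []), payload.get("notes", []))
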