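"""Curation filters for experimental stability-mutant tables.

Benchmark tables of point mutations carry measurement provenance that has
nothing to do with force-field quality: multi-site mutants, NMR or
low-resolution reference structures, residues coordinating metals or
cofactors, reverse mutations measured on mutant structures, and mutants
whose modelled structure shows large van der Waals clashes.  The filters
here remove those records in a documented order and report per-rule counts;
duplicate measurements of the same mutant are merged toward 25 degrees C
and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable

import numpy as np
import pandas as pd

#: filter order; each name doubles as the removal-reason key
FILTER_ORDER = (
    "multiple_mutations",
    "not_xray",
    "resolution",
    "metal_or_cofactor",
    "reverse_mutation",
    "clash",
)

RESOLUTION_CUTOFF = 2.5     # Angstrom
DEFAULT_CLASH_THRESHOLD = 5.0  # kcal/mol (a 6 kcal/mol variant is also used)
REFERENCE_TEMPERATURE = 25.0   # Celsius


@dataclass
class MutantRecord:
    """One experimental ddG measurement with curation provenance."""

    pdb_id: str
    chain: str
    wt_aa: str
    seq_number: int
    mut_aa: str
    ddg_exp: float                    # kcal/mol, destabilizing positive
    temperature: float = 25.0         # Celsius
    ph: float = 7.0
    method: str = "XRAY"
    resolution: float | None = None   # Angstrom
    n_mutations: int = 1
    has_metal_or_cofactor_contact: bool = False
    clash_energy: float = 0.0         # kcal/mol, from the mutation engine
    is_reverse_mutation: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.ddg_exp):
            raise ValueError("ddg_exp must be finite")
        if self.n_mutations < 1:
            raise ValueError("n_mutations must be >= 1")

    @property
    def key(self) -> tuple:
        return (self.pdb_id, self.chain, self.seq_number,
                self.wt_aa, self.mut_aa)


@dataclass
class CurationReport:
    retained: list[MutantRecord]
    removed_counts: dict[str, int] = field(default_factory=dict)
    n_input: int = 0

    def __post_init__(self) -> None:
        total = len(self.retained) + sum(self.removed_counts.values())
        if total != self.n_input:
            raise ValueError("removed + retained must equal input count")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": len(self.retained),
            "removed": dict(self.removed_counts),
        }


_RULES = {
    "multiple_mutations": lambda r, thr: r.n_mutations > 1,
    "not_xray": lambda r, thr: r.method.upper() != "XRAY",
    "resolution": lambda r, thr: (r.resolution is None
                                  or r.resolution > RESOLUTION_CUTOFF),
    "metal_or_cofactor": lambda r, thr: r.has_metal_or_cofactor_contact,
    "reverse_mutation": lambda r, thr: r.is_reverse_mutation,
    "clash": lambda r, thr: r.clash_energy > thr,
}


def _removal_reason(rec: MutantRecord, clash_threshold: float,
                    order: tuple[str, ...] = FILTER_ORDER) -> str | None:
    for name in order:
        if _RULES[name](rec, clash_threshold):
            return name
    return None


def filter_records(records: Iterable[MutantRecord],
                   clash_threshold: float = DEFAULT_CLASH_THRESHOLD,
                   order: tuple[str, ...] = FILTER_ORDER,
                   ) -> CurationReport:
    """Apply the curation filters; a record is removed under its first
    matching rule in ``order`` (the retained set is order-independent)."""
    records = list(records)
    counts = {name: 0 for name in order}
    counts["incomplete"] = 0
    retained = []
    for rec in records:
        if not isinstance(rec, MutantRecord):
            counts["incomplete"] += 1
            continue
        reason = _removal_reason(rec, clash_threshold, order)
        if reason is None:
            retained.append(rec)
        else:
            counts[reason] += 1
    counts = {k: v for k, v in counts.items() if v > 0 or k in order}
    return CurationReport(retained=retained, removed_counts=counts,
                          n_input=len(records))


def merge_duplicates(records: Iterable[MutantRecord]) -> list[MutantRecord]:
    """Collapse duplicate measurements of the same mutant.

    Within a (pdb, chain, position, wt, mut) key the records measured
    closest to 25 C are kept (ties keep all) and their ddG values averaged
    into a single record.
    """
    by_key: dict[tuple, list[MutantRecord]] = {}
    order: list[tuple] = []
    for rec in records:
        if rec.key not in by_key:
            order.append(rec.key)
        by_key.setdefault(rec.key, []).append(rec)
    out = []
    for key in order:
        group = by_key[key]
        if len(group) == 1:
            out.append(group[0])
            continue
        best = min(abs(r.temperature - REFERENCE_TEMPERATURE) for r in group)
        closest = [r for r in group
                   if abs(abs(r.temperature - REFERENCE_TEMPERATURE) - best)
                   < 1e-9]
        mean_ddg = float(np.mean([r.ddg_exp for r in closest]))
        merged = MutantRecord(**{f.name: getattr(closest[0], f.name)
                                 for f in fields(MutantRecord)})
        merged.ddg_exp = mean_ddg
        out.append(merged)
    return out


def curate(records: Iterable[MutantRecord],
           clash_threshold: float = DEFAULT_CLASH_THRESHOLD) -> CurationReport:
    """Full pipeline: merge duplicates, then filter. Idempotent."""
    records = list(records)
    merged = merge_duplicates(records)
    report = filter_records(merged, clash_threshold)
    dup = len(records) - len(merged)
    if dup:
        report.removed_counts["duplicate_merged"] = dup
    report.n_input = len(records)
    return report


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

TSV_COLUMNS = [f.name for f in fields(MutantRecord)]


def records_to_frame(records: Iterable[MutantRecord]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(r, c) for c in TSV_COLUMNS}
                         for r in records])


def read_records_tsv(path: str) -> list[MutantRecord]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in TSV_COLUMNS if c in df.columns}
        if "resolution" in kwargs and pd.isna(kwargs["resolution"]):
            kwargs["resolution"] = None
        for flag in ("has_metal_or_cofactor_contact", "is_reverse_mutation"):
            if flag in kwargs:
                kwargs[flag] = bool(kwargs[flag])
        for intcol in ("seq_number", "n_mutations"):
            if intcol in kwargs:
                kwargs[intcol] = int(kwargs[intcol])
        out.append(MutantRecord(**kwargs))
    return out


def write_records_tsv(records: Iterable[MutantRecord], path: str) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)
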