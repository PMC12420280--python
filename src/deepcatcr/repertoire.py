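"""Repertoire reading, CDR3 filtering, clone selection and clustering.

A repertoire is one donor's collection of clonotypes: a CDR3 amino-acid
string plus an abundance (clone count or frequency).  Preprocessing for
repertoire-level scoring follows the screening pipeline: quality filters on
the CDR3 strings, selection of expanded / top clones, and an optional
similarity clustering that enriches for putatively antigen-specific
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .encoding import MAX_CDR3_LENGTH, MIN_CDR3_LENGTH

__all__ = [
    "CloneRecord", "Repertoire", "FilterReport", "RepertoireFormatError",
    "filter_cdr3s", "select_expanded_clones", "select_top_clones",
    "cluster_cdr3s", "read_repertoire", "write_repertoire", "read_cluster_file",
]


class RepertoireFormatError(ValueError):
    """A repertoire file is missing required columns or has bad values."""


@dataclass
class CloneRecord:
    cdr3_aa: str
    count: float = 1.0


@dataclass
class Repertoire:
    sample_id: str
    clones: list[CloneRecord] = field(default_factory=list)
    label: str | None = None  # "cancer" | "healthy" | None (unknown)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.clones)

    @property
    def sequences(self) -> list[str]:
        return [c.cdr3_aa for c in self.clones]


@dataclass
class FilterReport:
    n_input: int = 0
    n_rejected_incomplete: int = 0
    n_rejected_nonproductive: int = 0
    n_rejected_length: int = 0
    n_rejected_public: int = 0
    n_retained: int = 0

    def check(self) -> None:
        total = (self.n_rejected_incomplete + self.n_rejected_nonproductive
                 + self.n_rejected_length + self.n_rejected_public
                 + self.n_retained)
        assert total == self.n_input, "filter report counts inconsistent"


def filter_cdr3s(
    sequences: list[str],
    min_len: int = MIN_CDR3_LENGTH,
    max_len: int = MAX_CDR3_LENGTH,
    public_set: set[str] | None = None,
) -> tuple[list[str], FilterReport]:
    """Apply the CDR3 quality filters, preserving input order.

    A retained sequence starts with C, ends with F, contains neither ``B``
    nor ``*`` (non-productive markers), has length within
    ``[min_len, max_len]``, and is absent from the optional set of sequences
    common in healthy individuals.  Each rejected sequence is assigned exactly
    one reason, checked in that order.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    public_set = public_set or set()
    report = FilterReport(n_input=len(sequences))
    kept: list[str] = []
    for seq in sequences:
        if not seq or seq[0] != "C" or seq[-1] != "F":
            report.n_rejected_incomplete += 1
        elif "B" in seq or "*" in seq:
            report.n_rejected_nonproductive += 1
        elif not (min_len <= len(seq) <= max_len):
            report.n_rejected_length += 1
        elif seq in public_set:
            report.n_rejected_public += 1
        else:
            kept.append(seq)
            report.n_retained += 1
    report.check()
    return kept, report


def filter_repertoire(
    repertoire: Repertoire,
    min_len: int = MIN_CDR3_LENGTH,
    max_len: int = MAX_CDR3_LENGTH,
    public_set: set[str] | None = None,
) -> tuple[Repertoire, FilterReport]:
    """Clone-level version of :func:`filter_cdr3s` (keeps counts attached)."""
    kept_seqs, report = filter_cdr3s(
        [c.cdr3_aa for c in repertoire.clones], min_len, max_len, public_set)
    kept_set: dict[str, int] = {}
    for s in kept_seqs:
        kept_set[s] = kept_set.get(s, 0) + 1
    clones = []
    for c in repertoire.clones:
        if kept_set.get(c.cdr3_aa, 0) > 0:
            kept_set[c.cdr3_aa] -= 1
            clones.append(c)
    return Repertoire(repertoire.sample_id, clones, repertoire.label,
                      dict(repertoire.metadata)), report


def select_expanded_clones(repertoire: Repertoire, fold: float = 4.0) -> Repertoire:
    """Keep clones whose abundance is >= ``fold`` times the repertoire minimum."""
    if not repertoire.clones:
        return Repertoire(repertoire.sample_id, [], repertoire.label,
                          dict(repertoire.metadata))
    threshold = fold * min(c.count for c in repertoire.clones)
    clones = [c for c in repertoire.clones if c.count >= threshold]
    return Repertoire(repertoire.sample_id, clones, repertoire.label,
                      dict(repertoire.metadata))


def select_top_clones(repertoire: Repertoire, n: int = 10_000) -> Repertoire:
    """Keep the ``n`` most abundant clones (ties broken lexicographically)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(repertoire.clones, key=lambda c: (-c.count, c.cdr3_aa))
    return Repertoire(repertoire.sample_id, ranked[:n], repertoire.label,
                      dict(repertoire.metadata))


def cluster_cdr3s(
    sequences: list[str],
    max_mismatch: int = 1,
    drop_singletons: bool = True,
) -> list[list[str]]:
    """Group similar same-length CDR3s by central-region Hamming distance.

    Two sequences belong to the same cluster (via single linkage) when they
    have equal length and differ at no more than ``max_mismatch`` positions
    over the central region (0-based positions 3 .. L-4, i.e. excluding the
    three conserved-ish residues at each end).  This is a deliberately simple
    stand-in for dedicated antigen-specificity clustering tools; externally
    produced cluster files are accepted via :func:`read_cluster_file`.
    """
    clusters: list[list[str]] = []
    by_length: dict[int, list[str]] = {}
    for s in sequences:
        by_length.setdefault(len(s), []).append(s)

    def close(a: str, b: str) -> bool:
        core = range(3, len(a) - 3)
        mism = sum(1 for i in core if a[i] != b[i])
        return mism <= max_mismatch

    for _, group in sorted(by_length.items()):
        # union-find over the group
        parent = list(range(len(group)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                if close(group[i], group[j]):
                    parent[find(i)] = find(j)
        members: dict[int, list[str]] = {}
        for i, s in enumerate(group):
            members.setdefault(find(i), []).append(s)
        for cl in members.values():
            if len(cl) > 1 or not drop_singletons:
                clusters.append(cl)
    return clusters


def clustered_subset(sequences: list[str], max_mismatch: int = 1) -> list[str]:
    """Union of all non-singleton clusters, input order preserved."""
    keep = set()
    for cl in cluster_cdr3s(sequences, max_mismatch=max_mismatch,
                            drop_singletons=True):
        keep.update(cl)
    return [s for s in sequences if s in keep]


# --------------------------------------------------------------------------
# Readers / writers
# --------------------------------------------------------------------------

_AIRR_COUNT_COLUMNS = ("duplicate_count", "consensus_count")
_IMMUNOSEQ_COUNT_COLUMNS = ("count (templates/reads)", "frequencyCount",
                            "frequencyCount (%)")


def _aggregate(df: pd.DataFrame, seq_col: str, count_col: str | None,
               sample_id: str, path: str | Path) -> Repertoire:
    if count_col is None:
        df = df.assign(_count=1.0)
        count_col = "_count"
    counts = pd.to_numeric(df[count_col], errors="coerce")
    bad = counts.isna() & df[count_col].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise RepertoireFormatError(
            f"{path}: unparseable count {df[count_col][bad.idxmax()]!r} at line {line}")
    agg = (
        pd.DataFrame({"cdr3_aa": df[seq_col].astype(str), "count": counts.fillna(0.0)})
        .groupby("cdr3_aa", sort=False)["count"].sum()
    )
    clones = [CloneRecord(cdr3_aa=s, count=float(c)) for s, c in agg.items()]
    return Repertoire(sample_id=sample_id, clones=clones)


def read_repertoire(path: str | Path, format: str = "airr",
                    sample_id: str | None = None) -> Repertoire:
    """Read one donor's repertoire file.

    ``format`` is one of ``airr`` (AIRR Rearrangement TSV: ``junction_aa``
    plus ``duplicate_count``/``consensus_count``), ``immunoseq``
    (``aminoAcid`` plus a template-count or frequency column) or ``plain``
    (one CDR3 per line, optional tab-separated count defaulting to 1).
    Duplicate CDR3s are aggregated by summing counts.
    """
    path = Path(path)
    sample_id = sample_id or path.stem
    if format == "plain":
        rows = []
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            count = 1.0
            if len(parts) > 1 and parts[1].strip():
                try:
                    count = float(parts[1])
                except ValueError as exc:
                    raise RepertoireFormatError(
                        f"{path}: unparseable count {parts[1]!r} at line {lineno}"
                    ) from exc
            rows.append((parts[0].strip(), count))
        agg: dict[str, float] = {}
        order: list[str] = []
        for s, c in rows:
            if s not in agg:
                agg[s] = 0.0
                order.append(s)
            agg[s] += c
        return Repertoire(sample_id, [CloneRecord(s, agg[s]) for s in order])

    df = pd.read_csv(path, sep="\t", dtype=str)
    if format == "airr":
        if "junction_aa" not in df.columns:
            raise RepertoireFormatError(f"{path}: missing column 'junction_aa'")
        count_col = next((c for c in _AIRR_COUNT_COLUMNS if c in df.columns), None)
        return _aggregate(df, "junction_aa", count_col, sample_id, path)
    if format == "immunoseq":
        if "aminoAcid" not in df.columns:
            raise RepertoireFormatError(f"{path}: missing column 'aminoAcid'")
        count_col = next((c for c in _IMMUNOSEQ_COUNT_COLUMNS if c in df.columns), None)
        return _aggregate(df, "aminoAcid", count_col, sample_id, path)
    raise ValueError(f"unknown repertoire format {format!r}")


def write_repertoire(repertoire: Repertoire, path: str | Path,
                     format: str = "airr") -> None:
    path = Path(path)
    if format == "airr":
        pd.DataFrame({
            "junction_aa": [c.cdr3_aa for c in repertoire.clones],
            "duplicate_count": [c.count for c in repertoire.clones],
        }).to_csv(path, sep="\t", index=False)
    elif format == "plain":
        path.write_text("".join(
            f"{c.cdr3_aa}\t{c.count:g}\n" for c in repertoire.clones))
    else:
        raise ValueError(f"unknown repertoire format {format!r}")


def read_cluster_file(path: str | Path) -> list[list[str]]:
    """Read an externally produced clustering (TSV: cluster_id, cdr3_aa)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("cluster_id", "cdr3_aa"):
        if col not in df.columns:
            raise RepertoireFormatError(f"{path}: missing column {col!r}")
    return [g["cdr3_aa"].tolist() for _, g in df.groupby("cluster_id", sort=True)]
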