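"""Synthetic CDR3 sequences, labeled training sets and donor cohorts.

The generator emulates the structure of beta-chain CDR3 data: strings start
with the conserved cysteine and end with the conserved phenylalanine, lengths
fall in [11, 20] with a peaked distribution, interior residues are drawn from
a background alphabet, and class signal is carried by short planted k-mer
motifs.  Donor repertoires add clone abundances drawn from a heavy-tailed
(power-law) law and a small antigen-specific fraction, mirroring the fact
that tumour-reactive clonotypes are a tiny minority of a blood repertoire.

Two cohort modes exist:

* ``planted_fraction`` — cancer donors carry a fraction ``ca_fraction`` of
  motif-bearing clones, healthy donors none: the mean repertoire scorer
  separates the groups.
* ``matched_mean`` — healthy donors carry only "ambiguous" motif clones
  (trained to score near 0.5 via 50/50 labels), cancer donors carry a
  per-donor Uniform(0.35, 0.65) mixture of strong-motif and background
  clones: group means coincide but score dispersion differs, the regime in
  which the variance scorer dominates the mean scorer.

A companion generator produces synthetic AAindex-style biochemical property
tables from a low-rank latent-factor model, emulating the strong mutual
correlation of real amino-acid property scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import AAindexTable, CANONICAL_RESIDUES
from .repertoire import CloneRecord, Repertoire

__all__ = [
    "FixtureSpec", "generate_cdr3", "generate_labeled_dataset",
    "generate_cohort", "make_synthetic_aaindex_tables",
    "write_aaindex_flatfile", "write_cohort", "read_cohort_manifest",
]

_INTERIOR_LETTERS = [r for r in CANONICAL_RESIDUES if r not in "CF"]

#: default CDR3 length law: peaked around 14-15, support 11..20
_DEFAULT_LENGTH_WEIGHTS = {
    11: 1, 12: 2, 13: 4, 14: 6, 15: 6, 16: 4, 17: 3, 18: 2, 19: 1, 20: 1,
}


def _default_background() -> dict[str, float]:
    # interior alphabet: uniform over the 18 non-C/F letters, with C and F
    # present at low rates (they do occur inside real CDR3s)
    freqs = {r: 0.98 / 18 for r in _INTERIOR_LETTERS}
    freqs["C"] = 0.01
    freqs["F"] = 0.01
    return freqs


@dataclass
class FixtureSpec:
    """All knobs of the synthetic generator (a pure function of spec + seed)."""

    seed: int = 0
    length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_LENGTH_WEIGHTS))
    #: (motif, (min_start, max_start) over interior 0-based positions or None,
    #: planting probability)
    positive_motifs: list[tuple] = field(
        default_factory=lambda: [("LGQ", None, 1.0)])
    ambiguous_motif: str = "NDT"
    background_frequencies: dict[str, float] = field(
        default_factory=_default_background)
    clone_count_law: str = "power_law"
    power_law_alpha: float = 2.0
    ca_fraction: float = 0.05

    def __post_init__(self):
        lengths = sorted(self.length_distribution)
        if lengths[0] < 11 or lengths[-1] > 20:
            raise ValueError("length support must lie within [11, 20]")
        total = sum(self.length_distribution.values())
        self.length_distribution = {
            k: v / total for k, v in self.length_distribution.items()}
        total = sum(self.background_frequencies.values())
        self.background_frequencies = {
            k: v / total for k, v in self.background_frequencies.items()}
        if not 0.0 <= self.ca_fraction <= 1.0:
            raise ValueError("ca_fraction must be in [0, 1]")
        for motif, _, _ in self.positive_motifs:
            if len(motif) > 11 - 2:
                raise ValueError(f"motif {motif!r} longer than shortest interior")


def _sample_length(spec: FixtureSpec, rng: np.random.Generator) -> int:
    lengths = np.array(sorted(spec.length_distribution))
    probs = np.array([spec.length_distribution[i] for i in lengths])
    return int(rng.choice(lengths, p=probs))


def generate_cdr3(spec: FixtureSpec, rng: np.random.Generator,
                  motif: str | None = None,
                  position_range: tuple[int, int] | None = None) -> str:
    """One CDR3-like string; optionally overwrite an interior window with a motif."""
    n = _sample_length(spec, rng)
    letters = np.array(sorted(spec.background_frequencies))
    probs = np.array([spec.background_frequencies[l] for l in letters])
    interior = list(rng.choice(letters, size=n - 2, p=probs))
    if motif is not None:
        if len(motif) > n - 2:
            raise ValueError(f"motif {motif!r} longer than interior of length {n - 2}")
        hi = n - 2 - len(motif)
        lo = 0
        if position_range is not None:
            lo, hi = max(0, position_range[0]), min(hi, position_range[1])
            if lo > hi:
                raise ValueError("empty insertion window for motif")
        start = int(rng.integers(lo, hi + 1))
        interior[start:start + len(motif)] = list(motif)
    return "C" + "".join(interior) + "F"


def _contains_any(seq: str, motifs: list[str]) -> bool:
    return any(m in seq for m in motifs)


def _background_sequence(spec: FixtureSpec, rng: np.random.Generator,
                         forbidden: list[str], max_retries: int = 200) -> str:
    for _ in range(max_retries):
        s = generate_cdr3(spec, rng)
        if not _contains_any(s, forbidden):
            return s
    raise ValueError(
        "rejection sampling exhausted: forbidden motifs too frequent in background")


def _positive_sequence(spec: FixtureSpec, rng: np.random.Generator) -> str:
    motif, pos_range, prob = spec.positive_motifs[
        int(rng.integers(len(spec.positive_motifs)))]
    plant = rng.random() < prob
    forbidden = [spec.ambiguous_motif]
    if not plant:
        return _background_sequence(spec, rng,
                                    forbidden + [m for m, _, _ in spec.positive_motifs])
    for _ in range(200):
        s = generate_cdr3(spec, rng, motif=motif, position_range=pos_range)
        if spec.ambiguous_motif not in s:
            return s
    raise ValueError("could not plant motif without the ambiguous motif")


def _ambiguous_sequence(spec: FixtureSpec, rng: np.random.Generator) -> str:
    forbidden = [m for m, _, _ in spec.positive_motifs]
    for _ in range(200):
        s = generate_cdr3(spec, rng, motif=spec.ambiguous_motif)
        if not _contains_any(s, forbidden):
            return s
    raise ValueError("could not plant ambiguous motif cleanly")


def generate_labeled_dataset(
    n_pos: int, n_neg: int, spec: FixtureSpec | None = None,
    seed: int | None = None, n_ambiguous: int = 0,
) -> tuple[list[str], np.ndarray]:
    """Labeled CDR3 strings: motif-planted positives, motif-free negatives.

    ``n_ambiguous`` extra sequences carry the ambiguous motif and receive
    Bernoulli(1/2) labels; a model trained with cross-entropy learns to score
    them near 0.5, which the matched-mean cohort mode exploits.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    forbidden = [m for m, _, _ in spec.positive_motifs] + [spec.ambiguous_motif]
    seqs: list[str] = []
    labels: list[int] = []
    for _ in range(n_pos):
        seqs.append(_positive_sequence(spec, rng))
        labels.append(1)
    for _ in range(n_neg):
        seqs.append(_background_sequence(spec, rng, forbidden))
        labels.append(0)
    for _ in range(n_ambiguous):
        seqs.append(_ambiguous_sequence(spec, rng))
        labels.append(int(rng.random() < 0.5))
    order = rng.permutation(len(seqs))
    return [seqs[i] for i in order], np.array(labels)[order]


def _clone_count(spec: FixtureSpec, rng: np.random.Generator) -> float:
    if spec.clone_count_law == "uniform":
        return float(rng.integers(1, 101))
    if spec.clone_count_law == "power_law":
        # Pareto tail: P(count > c) ~ c^-(alpha-1); integer counts >= 1
        return float(np.floor(rng.pareto(spec.power_law_alpha - 1.0)) + 1.0)
    raise ValueError(f"unknown clone_count_law {spec.clone_count_law!r}")


def generate_cohort(
    n_cancer: int, n_healthy: int, clones_per_repertoire: int,
    spec: FixtureSpec | None = None, seed: int | None = None,
    mode: str = "planted_fraction",
    mixture_center: float = 0.5, mixture_halfwidth: float = 0.15,
) -> list[Repertoire]:
    """Labeled donor repertoires with controlled motif content.

    ``planted_fraction``: cancer donors have a ``ca_fraction`` of
    motif-bearing clones; healthy donors none.  ``matched_mean``: cancer
    donors mix strong-motif and background clones with a per-donor fraction
    drawn from Uniform(center - halfwidth, center + halfwidth); healthy
    donors carry only ambiguous-motif clones.  Callers match the group score
    means by calibrating ``mixture_center`` against the scoring model (the
    fraction at which the mixture's expected score equals the
    ambiguous-clone score); see module docstring.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    forbidden = [m for m, _, _ in spec.positive_motifs] + [spec.ambiguous_motif]
    cohort: list[Repertoire] = []

    def make(sample_id: str, label: str, motif_prob: float,
             healthy_kind: str) -> Repertoire:
        clones = []
        for _ in range(clones_per_repertoire):
            if label == "cancer":
                if rng.random() < motif_prob:
                    s = _positive_sequence(spec, rng)
                else:
                    s = _background_sequence(spec, rng, forbidden)
            else:
                if healthy_kind == "ambiguous":
                    s = _ambiguous_sequence(spec, rng)
                else:
                    s = _background_sequence(spec, rng, forbidden)
            clones.append(CloneRecord(s, _clone_count(spec, rng)))
        return Repertoire(sample_id=sample_id, clones=clones, label=label)

    for i in range(n_cancer):
        if mode == "planted_fraction":
            prob = spec.ca_fraction
        elif mode == "matched_mean":
            lo = max(0.0, mixture_center - mixture_halfwidth)
            hi = min(1.0, mixture_center + mixture_halfwidth)
            prob = float(rng.uniform(lo, hi))
        else:
            raise ValueError(f"unknown cohort mode {mode!r}")
        cohort.append(make(f"cancer_{i:03d}", "cancer", prob, ""))
    healthy_kind = "ambiguous" if mode == "matched_mean" else "background"
    for i in range(n_healthy):
        cohort.append(make(f"healthy_{i:03d}", "healthy", 0.0, healthy_kind))
    return cohort


# --------------------------------------------------------------------------
# Synthetic biochemical property tables
# --------------------------------------------------------------------------

def make_synthetic_aaindex_tables(
    n_indices: int = 553,
    n_factors: int = 8,
    noise_sd: float = 0.25,
    seed: int = 0,
    missing_fraction: float = 0.0,
) -> list[AAindexTable]:
    """Synthetic amino-acid property scales from a latent-factor model.

    Real biochemical scales are highly mutually correlated (hydrophobicity,
    size, charge and a few other latent properties dominate), which is why a
    handful of principal components captures most of their variance.  Each
    synthetic index is a random mixture of ``n_factors`` latent residue
    factors with geometrically decaying strengths (0.85^f) plus idiosyncratic
    noise of standard deviation ``noise_sd`` on the standardised scale.

    ``missing_fraction`` marks a random subset of indices incomplete (one
    residue value set to NaN) to exercise the drop-incomplete rule.
    """
    rng = np.random.default_rng(seed)
    factors = rng.standard_normal((n_factors, 20))
    strengths = 0.85 ** np.arange(n_factors)
    tables: list[AAindexTable] = []
    for i in range(n_indices):
        w = rng.standard_normal(n_factors) * strengths
        values = w @ factors + noise_sd * rng.standard_normal(20)
        vmap = dict(zip(CANONICAL_RESIDUES, values.astype(float)))
        if missing_fraction > 0 and rng.random() < missing_fraction:
            victim = str(rng.choice(list(CANONICAL_RESIDUES)))
            vmap[victim] = float("nan")
        tables.append(AAindexTable(index_id=f"SYNTH{i + 1:04d}", values=vmap))
    return tables


def write_aaindex_flatfile(tables: list[AAindexTable], path) -> None:
    """Write tables in the AAindex1 flat-file layout (H/I records, // ends)."""
    order = "ARNDCQEGHILKMFPSTWYV"
    with open(path, "w") as fh:
        for t in tables:
            fh.write(f"H {t.index_id}\n")
            fh.write("D synthetic property scale\n")
            fh.write("I    A/L     R/K     N/M     D/F     C/P     "
                     "Q/S     E/T     G/W     H/Y     I/V\n")
            vals = [t.values.get(r, float("nan")) for r in order]
            for half in (vals[:10], vals[10:]):
                fh.write("".join(
                    "      NA" if np.isnan(v) else f"{v:8.3f}" for v in half) + "\n")
            fh.write("//\n")


# --------------------------------------------------------------------------
# Cohort writers / manifest
# --------------------------------------------------------------------------

def write_cohort(repertoires: list[Repertoire], out_dir,
                 format: str = "airr") -> "Path":
    """Write one file per donor plus a manifest TSV (sample_id, path, label)."""
    from pathlib import Path
    from .repertoire import write_repertoire

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rep in repertoires:
        fname = f"{rep.sample_id}.tsv"
        write_repertoire(rep, out_dir / fname, format=format)
        rows.append((rep.sample_id, fname, rep.label or "unknown"))
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("sample_id\tpath\tlabel\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")
    return manifest


def read_cohort_manifest(manifest_path, format: str = "airr") -> list[Repertoire]:
    from pathlib import Path
    import pandas as pd
    from .repertoire import read_repertoire

    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t", dtype=str)
    for col in ("sample_id", "path", "label"):
        if col not in df.columns:
            raise ValueError(f"{manifest_path}: manifest missing column {col!r}")
    reps = []
    for _, row in df.iterrows():
        rep = read_repertoire(manifest_path.parent / row["path"], format=format,
                              sample_id=row["sample_id"])
        rep.label = row["label"] if row["label"] != "unknown" else None
        reps.append(rep)
    return reps
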