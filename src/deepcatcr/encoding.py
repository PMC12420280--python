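"""Amino-acid biochemical encoding of CDR3 sequences.

A CDR3 amino-acid string is mapped to a fixed-size numeric matrix by looking
up, for each residue, its coordinates on the top principal components of a
large collection of biochemical property scales (AAindex-style indices).
Each scale assigns one real number to each of the 20 canonical residues;
scales are standardised across residues and PCA reduces them to
``n_components`` (default 15) coordinates per residue.  Sequences shorter
than the padded length (20) are post-padded with zero rows, giving the
20 x 15 input matrix consumed by the classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
# residue order used by AAindex1 value lines
_AAINDEX_ORDER = "ARNDCQEGHILKMFPSTWYV"

MIN_CDR3_LENGTH = 11
MAX_CDR3_LENGTH = 20
PADDED_LENGTH = 20
N_COMPONENTS = 15


class EncodingError(ValueError):
    """A CDR3 string cannot be encoded (length or alphabet violation)."""


class AAindexFormatError(ValueError):
    """An AAindex flat file or table violates the expected format."""


class ProjectionConfigError(ValueError):
    """Not enough complete indices (or bad options) to build a projection."""


@dataclass
class AAindexTable:
    """One biochemical property scale: a value per canonical residue."""

    index_id: str
    values: dict[str, float]

    def is_complete(self) -> bool:
        return all(
            r in self.values and np.isfinite(self.values[r])
            for r in CANONICAL_RESIDUES
        )


@dataclass
class AminoAcidProjection:
    """Residue-to-feature lookup: 20 residues x n_components loadings."""

    loadings: pd.DataFrame  # index: residue letters, columns: PC1..PCn
    explained_variance_ratio: np.ndarray
    n_source_indices: int

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def cumulative_variance(self) -> float:
        return float(np.sum(self.explained_variance_ratio))

    def row(self, residue: str) -> np.ndarray:
        return self.loadings.loc[residue].to_numpy()


@dataclass
class EncodedSequence:
    """Zero-padded numeric matrix for one CDR3 plus its true length."""

    matrix: np.ndarray  # (PADDED_LENGTH, n_components)
    true_length: int
    sequence: str = field(default="")


# --------------------------------------------------------------------------
# AAindex flat-file reader
# --------------------------------------------------------------------------

def read_aaindex(path: str | Path) -> list[AAindexTable]:
    """Parse an AAindex1 flat file into property tables.

    Records are delimited by ``//``; the ``I`` header line is followed by two
    rows of ten values in AAindex residue order.  ``NA`` entries become NaN
    (the table is then incomplete and excluded from PCA).
    """
    tables: list[AAindexTable] = []
    index_id = ""
    pending: list[float] | None = None
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if line.startswith("H "):
                index_id = line[2:].strip()
            elif line.startswith("I "):
                pending = []
            elif line.startswith("//"):
                if pending is not None:
                    if len(pending) != 20:
                        raise AAindexFormatError(
                            f"record {index_id!r} ending at line {lineno}: "
                            f"expected 20 values, found {len(pending)}"
                        )
                    tables.append(AAindexTable(
                        index_id=index_id,
                        values=dict(zip(_AAINDEX_ORDER, pending)),
                    ))
                index_id, pending = "", None
            elif pending is not None and len(pending) < 20:
                for tok in line.split():
                    pending.append(np.nan if tok.upper() == "NA" else float(tok))
    return tables


# --------------------------------------------------------------------------
# Projection construction
# --------------------------------------------------------------------------

def build_projection(
    tables: list[AAindexTable],
    n_components: int = N_COMPONENTS,
) -> AminoAcidProjection:
    """PCA of the standardised residue-by-index matrix.

    Incomplete indices (any missing residue value) are dropped.  Each index
    is standardised to zero mean / unit variance across the 20 residues, the
    residues act as observations, and the per-residue scores on the top
    ``n_components`` components become the encoding rows.  Each component's
    sign is flipped so its largest-magnitude loading is positive, which makes
    the projection deterministic.
    """
    for t in tables:
        bad = set(t.values) - set(CANONICAL_RESIDUES)
        if bad:
            raise AAindexFormatError(
                f"index {t.index_id!r} has non-canonical residue letters: {sorted(bad)}"
            )
    complete = [t for t in tables if t.is_complete()]
    if len(complete) < n_components:
        raise ProjectionConfigError(
            f"need at least {n_components} complete indices, found {len(complete)}"
        )
    # residues as rows (observations), indices as columns (features)
    mat = np.array(
        [[t.values[r] for t in complete] for r in CANONICAL_RESIDUES],
        dtype=np.float64,
    )
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=0)
    if np.any(sd == 0):
        keep = sd > 0
        mat, mu, sd = mat[:, keep], mu[keep], sd[keep]
        if mat.shape[1] < n_components:
            raise ProjectionConfigError(
                "too few non-constant indices after dropping zero-variance scales"
            )
    z = (mat - mu) / sd

    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(z)  # (20, n_components)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(n_components):
        col = scores[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            scores[:, j] = -col
    loadings = pd.DataFrame(
        scores,
        index=list(CANONICAL_RESIDUES),
        columns=[f"PC{j + 1}" for j in range(n_components)],
    )
    return AminoAcidProjection(
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        n_source_indices=len(complete),
    )


def save_projection(projection: AminoAcidProjection, path: str | Path) -> None:
    """Write the projection as TSV plus a JSON metadata sidecar."""
    path = Path(path)
    projection.loadings.to_csv(path, sep="\t", index_label="residue",
                               float_format="%.10g")
    meta = {
        "explained_variance_ratio": projection.explained_variance_ratio.tolist(),
        "cumulative_variance": projection.cumulative_variance,
        "n_source_indices": projection.n_source_indices,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=1))


def load_projection(path: str | Path) -> AminoAcidProjection:
    path = Path(path)
    loadings = pd.read_csv(path, sep="\t", index_col="residue")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        evr = np.asarray(meta["explained_variance_ratio"], dtype=float)
        n_src = int(meta["n_source_indices"])
    else:
        evr = np.full(loadings.shape[1], np.nan)
        n_src = -1
    missing = set(CANONICAL_RESIDUES) - set(loadings.index)
    if missing:
        raise AAindexFormatError(f"projection missing residues: {sorted(missing)}")
    return AminoAcidProjection(
        loadings=loadings.loc[list(CANONICAL_RESIDUES)],
        explained_variance_ratio=evr,
        n_source_indices=n_src,
    )


def default_projection() -> AminoAcidProjection:
    """The projection shipped with the package.

    Built from a synthetic 553-scale biochemical index table (see
    :mod:`deepcatcr.simulate`); users with the real AAindex1 flat file can
    rebuild a faithful projection with ``deepcatcr build-encoding``.
    """
    ref = resources.files("deepcatcr").joinpath("data/default_projection.tsv")
    with resources.as_file(ref) as p:
        return load_projection(p)


def fixture_projection() -> AminoAcidProjection:
    """A random-but-fixed projection with distinct rows, for tests."""
    ref = resources.files("deepcatcr").joinpath("data/fixture_projection.tsv")
    with resources.as_file(ref) as p:
        return load_projection(p)


# --------------------------------------------------------------------------
# Sequence encoding
# --------------------------------------------------------------------------

def encode_cdr3(
    sequence: str,
    projection: AminoAcidProjection,
    min_len: int = MIN_CDR3_LENGTH,
    max_len: int = MAX_CDR3_LENGTH,
) -> EncodedSequence:
    """Encode one CDR3 string as a zero-padded matrix.

    Row ``i`` is the projection row of residue ``i``; rows beyond the true
    length are exactly zero (post-padding).
    """
    n = len(sequence)
    if not (min_len <= n <= max_len):
        raise EncodingError(
            f"sequence {sequence!r} has length {n}, outside [{min_len}, {max_len}]"
        )
    bad = set(sequence) - set(CANONICAL_RESIDUES)
    if bad:
        raise EncodingError(
            f"sequence {sequence!r} contains non-canonical letters: {sorted(bad)}"
        )
    matrix = np.zeros((PADDED_LENGTH, projection.n_components))
    matrix[:n] = projection.loadings.loc[list(sequence)].to_numpy()
    return EncodedSequence(matrix=matrix, true_length=n, sequence=sequence)


def decode_matrix(matrix: np.ndarray, projection: AminoAcidProjection) -> str:
    """Nearest-row decoding (inverse of :func:`encode_cdr3` when rows are distinct)."""
    rows = projection.loadings.to_numpy()
    letters = projection.loadings.index.to_numpy()
    out = []
    for r in matrix:
        if np.allclose(r, 0.0):
            break
        out.append(letters[np.argmin(np.linalg.norm(rows - r, axis=1))])
    return "".join(out)


class CDR3Encoder(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer: CDR3 strings -> (n, 20, n_components) array.

    Parameters
    ----------
    projection : AminoAcidProjection or None
        Residue lookup; ``None`` selects the packaged default projection.
    """

    def __init__(self, projection: AminoAcidProjection | None = None):
        self.projection = projection

    def fit(self, X, y=None):
        self.projection_ = (
            self.projection if self.projection is not None else default_projection()
        )
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "projection_"):
            self.fit(X)
        encoded = [encode_cdr3(s, self.projection_) for s in X]
        return np.stack([e.matrix for e in encoded]) if encoded else np.empty(
            (0, PADDED_LENGTH, self.projection_.n_components))
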