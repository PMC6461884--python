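"""Trinucleotide substitution catalogs and signature refitting.

Catalogs use the canonical pyrimidine-strand convention: 6 substitution
types (C>A, C>G, C>T, T>A, T>C, T>G) x 16 flanking-base combinations,
giving 96 classes labelled like ``"A[C>T]G"``.  The index order is fixed:
substitution-major, then 5' base, then 3' base, each in A, C, G, T order —
the ordering used by the common reference-signature text files, which are
accepted as drop-in input.

Refitting decomposes a catalog against a fixed signature matrix by
non-negative least squares (no sparsity selection); exposures are
renormalised to sum to one and the cosine similarity of the
reconstruction is reported.  Contributions above a 5% threshold are
considered significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import nnls

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")

#: the 96 context classes in canonical order
CONTEXTS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS for five in _BASES for three in _BASES
)
_CONTEXT_INDEX = {c: i for i, c in enumerate(CONTEXTS_96)}


def build_context_catalog(context_classes: Iterable[str]) -> np.ndarray:
    """Histogram a list of SNV context classes into a 96-vector.

    Raises ``ValueError`` naming the first unknown class label.
    """
    counts = np.zeros(96, dtype=int)
    for c in context_classes:
        try:
            counts[_CONTEXT_INDEX[c]] += 1
        except KeyError:
            raise ValueError(f"unknown trinucleotide context class: {c!r}") from None
    return counts


@dataclass
class SignatureSet:
    """96 x K matrix of reference signatures, columns summing to one."""

    matrix: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.names)):
            raise ValueError(
                f"signature matrix must be 96 x {len(self.names)}, got {self.matrix.shape}")
        if (self.matrix < 0).any():
            raise ValueError("signature matrix entries must be non-negative")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("signature columns must sum to 1 (+/- 1e-6)")

    @property
    def k(self) -> int:
        return len(self.names)


@dataclass
class Exposures:
    values: np.ndarray            # K-vector, non-negative, sums to 1
    names: tuple[str, ...]
    cosine: float                 # reconstruction cosine similarity

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names), name="exposure")


def refit_exposures(catalog: np.ndarray, signatures: SignatureSet) -> Exposures:
    """Non-negative least-squares refit of a catalog onto fixed signatures.

    Deterministic; the catalog is normalised to a frequency vector before
    fitting and the exposures renormalised to sum to one.
    """
    catalog = np.asarray(catalog, dtype=float)
    if catalog.shape != (96,):
        raise ValueError(f"catalog must be a 96-vector, got shape {catalog.shape}")
    total = catalog.sum()
    if total <= 0:
        raise ValueError("catalog is empty: nothing to refit")
    target = catalog / total
    coef, _ = nnls(signatures.matrix, target)
    recon = signatures.matrix @ coef
    denom = np.linalg.norm(recon) * np.linalg.norm(target)
    cosine = float(recon @ target / denom) if denom > 0 else 0.0
    s = coef.sum()
    values = coef / s if s > 0 else coef
    return Exposures(values, signatures.names, cosine)


def significant_signatures(exposures: Exposures,
                           threshold: float = 0.05) -> list[tuple[str, float]]:
    """Signatures with exposure strictly above *threshold*, descending."""
    pairs = [(n, float(v)) for n, v in zip(exposures.names, exposures.values)
             if v > threshold]
    return sorted(pairs, key=lambda p: (-p[1], p[0]))


# -- signature matrix I/O ---------------------------------------------------


def read_signature_tsv(path) -> SignatureSet:
    """Read a 96 x K signature matrix from TSV.

    The first column holds context labels (``A[C>A]A`` style); remaining
    columns are signatures.  Rows may come in any order.  Extra annotation
    columns named "Substitution Type"/"Trinucleotide"/"Somatic Mutation
    Type" (the reference-file dialect) are also understood.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.strip().lower(): c for c in df.columns}
    if "somatic mutation type" in cols:
        labels = df[cols["somatic mutation type"]]
        drop = [cols[k] for k in
                ("substitution type", "trinucleotide", "somatic mutation type")
                if k in cols]
        df = df.drop(columns=drop)
    else:
        labels = df.iloc[:, 0]
        df = df.iloc[:, 1:]
    df.index = [str(x).strip() for x in labels]
    missing = set(CONTEXTS_96) - set(df.index)
    if missing:
        raise ValueError(f"signature file lacks {len(missing)} context rows, "
                         f"e.g. {sorted(missing)[:3]}")
    df = df.loc[list(CONTEXTS_96)]
    mat = df.to_numpy(dtype=float)
    mat = mat / mat.sum(axis=0, keepdims=True)
    return SignatureSet(mat, tuple(str(c) for c in df.columns))


def write_signature_tsv(signatures: SignatureSet, path) -> None:
    df = pd.DataFrame(signatures.matrix, index=list(CONTEXTS_96),
                      columns=list(signatures.names))
    df.to_csv(path, sep="\t", index_label="context")


def load_fixture_signatures() -> tuple[np.ndarray, tuple[str, ...]]:
    """Load the packaged 4-signature synthetic fixture as (matrix, names)."""
    ref = resources.files("tgcevo.data").joinpath("signatures4.tsv")
    with resources.as_file(ref) as path:
        sigset = read_signature_tsv(path)
    return sigset.matrix, sigset.names


def fixture_signature_set() -> SignatureSet:
    mat, names = load_fixture_signatures()
    return SignatureSet(mat, names)


def make_fixture_signatures(seed: int = 20190211, k: int = 4) -> SignatureSet:
    """Deterministically generate the synthetic signature fixture.

    Sparse Dirichlet columns are close to mutually orthogonal, which makes
    mixture recovery well conditioned in tests.
    """
    rng = np.random.default_rng(seed)
    mat = rng.dirichlet(np.full(96, 0.15), size=k).T
    names = tuple(f"SIG{chr(ord('A') + i)}" for i in range(k))
    return SignatureSet(mat, names)
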