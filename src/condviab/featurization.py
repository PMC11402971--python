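"""Compound and transcriptome featurization.

Compounds are encoded as 512-bit Morgan (ECFP-like, radius 2) fingerprints
with the micromolar assay concentration appended as a 513th feature.
Expression matrices (samples x genes) are z-scored per gene, with the
training-cohort statistics frozen for reuse on new cohorts, and can be
harmonized onto a reference gene axis with mean imputation of missing genes.
Cross-validation folds are grouped by sample (cell line) so no cell line
ever appears on both sides of a split.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.base import BaseEstimator, TransformerMixin

PAIR_DELIMITERS = (";;", "..")

__all__ = [
    "CompoundRecord", "FeaturizationError", "CompoundFeaturizer",
    "ExpressionStandardizer", "featurize_compound", "morgan_bits",
    "straw_bits", "standardize_expression", "harmonize_genes",
    "make_cv_splits", "load_compound_table", "load_expression",
]


class FeaturizationError(ValueError):
    pass


@dataclass
class CompoundRecord:
    """One screened compound (or compound pair, SMILES joined by ';;')."""
    compound_id: str
    smiles: str
    moa_class: str | None = None
    nominal_targets: list[str] = field(default_factory=list)


def _parse_structures(record: CompoundRecord):
    smiles = record.smiles
    parts = [smiles]
    for delim in PAIR_DELIMITERS:
        if delim in smiles:
            parts = smiles.split(delim)
            break
    mols = []
    for s in parts:
        mol = Chem.MolFromSmiles(s.strip())
        if mol is None:
            raise FeaturizationError(
                f"unparseable SMILES for compound {record.compound_id!r}: {s!r}")
        mols.append(mol)
    return mols


def morgan_bits(record: CompoundRecord, n_bits: int = 512,
                radius: int = 2) -> np.ndarray:
    """Folded Morgan fingerprint; compound pairs are combined bitwise-OR."""
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=radius, fpSize=n_bits)
    bits = np.zeros(n_bits, dtype=np.float32)
    for mol in _parse_structures(record):
        fp = gen.GetFingerprintAsNumPy(mol)
        bits = np.maximum(bits, fp.astype(np.float32))
    return bits


def featurize_compound(record: CompoundRecord, concentration_um: float,
                       n_bits: int = 512, radius: int = 2,
                       log_concentration: bool = False) -> np.ndarray:
    """Morgan bits + concentration -> length ``n_bits + 1`` feature vector.

    Concentration enters un-logged (micromolar) by default as the final
    element; ``log_concentration`` switches to log10 uM.
    """
    if not np.isfinite(concentration_um) or concentration_um <= 0:
        raise ValueError(
            f"concentration must be positive, got {concentration_um!r} "
            f"for compound {record.compound_id!r}")
    bits = morgan_bits(record, n_bits=n_bits, radius=radius)
    conc = np.log10(concentration_um) if log_concentration else concentration_um
    return np.concatenate([bits, np.asarray([conc], dtype=np.float64)])


def straw_bits(compound_id: str, n_bits: int = 512, seed: int = 0) -> np.ndarray:
    """Structure-free random binary code for a compound, used by the straw
    (structural-ablation) model.  Deterministic in (compound_id, seed) and
    independent of call order."""
    digest = hashlib.blake2b(f"{seed}:{compound_id}".encode(),
                             digest_size=8).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "little"))
    return (rng.random(n_bits) < 0.5).astype(np.float32)


class CompoundFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer from (record, concentration) pairs to compound vectors.

    ``transform`` takes a sequence of ``(CompoundRecord, concentration_um)``
    tuples and returns an ``(n, n_bits + 1)`` array.  Fingerprints are cached
    per compound_id, so dose grids over the same compound are cheap.
    """

    def __init__(self, n_bits: int = 512, radius: int = 2,
                 log_concentration: bool = False):
        self.n_bits = n_bits
        self.radius = radius
        self.log_concentration = log_concentration

    def fit(self, X=None, y=None):
        self.cache_: dict[str, np.ndarray] = {}
        return self

    def transform(self, X):
        if not hasattr(self, "cache_"):
            self.fit()
        rows = []
        for record, conc in X:
            if record.compound_id not in self.cache_:
                self.cache_[record.compound_id] = morgan_bits(
                    record, self.n_bits, self.radius)
            if not np.isfinite(conc) or conc <= 0:
                raise ValueError(
                    f"concentration must be positive, got {conc!r} for "
                    f"compound {record.compound_id!r}")
            c = np.log10(conc) if self.log_concentration else conc
            rows.append(np.concatenate([self.cache_[record.compound_id], [c]]))
        return np.asarray(rows, dtype=np.float64)


class ExpressionStandardizer(BaseEstimator, TransformerMixin):
    """Per-gene z-scoring with frozen training statistics.

    Spread is the population standard deviation (divisor N).  Zero-spread
    genes transform to all-zeros (scale stored as 1) with a warning, keeping
    the gene axis fixed across cohorts.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D matrix with >= 2 samples to fit")
        self.mean_ = X.mean(axis=0)
        spread = X.std(axis=0)  # population (ddof=0)
        self.zero_spread_ = spread == 0
        if self.zero_spread_.any():
            warnings.warn(
                f"{int(self.zero_spread_.sum())} zero-spread gene(s) set to 0",
                stacklevel=2)
        self.scale_ = np.where(self.zero_spread_, 1.0, spread)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=np.float64)
        Z = (X - self.mean_) / self.scale_
        Z[:, self.zero_spread_] = 0.0
        return Z

    def inverse_transform(self, Z):
        Z = np.asarray(Z, dtype=np.float64)
        return Z * self.scale_ + self.mean_


def standardize_expression(matrix: pd.DataFrame,
                           stats: tuple[np.ndarray, np.ndarray] | None = None):
    """z-score a samples x genes frame per gene.

    With ``stats=None`` the matrix's own (mean, spread) are used and returned
    for reuse; otherwise the supplied frozen training statistics are applied
    unchanged.  Returns ``(standardized_frame, (mean, spread))``.
    """
    values = matrix.to_numpy(dtype=np.float64)
    if stats is None:
        std = ExpressionStandardizer().fit(values)
        mean, scale = std.mean_, std.scale_
        zero = std.zero_spread_
    else:
        mean, scale = (np.asarray(s, dtype=np.float64) for s in stats)
        zero = scale == 0
        scale = np.where(zero, 1.0, scale)
    Z = (values - mean) / scale
    Z[:, zero] = 0.0
    out = pd.DataFrame(Z, index=matrix.index, columns=matrix.columns)
    return out, (mean, np.where(zero, 0.0, scale))


def harmonize_genes(matrix: pd.DataFrame, reference_genes: list[str],
                    reference_means: np.ndarray | None = None,
                    min_matched: float = 0.5):
    """Project a cohort onto a reference gene axis.

    Genes present are copied; absent genes are filled with the reference
    per-gene mean (0 for a standardized reference).  Returns the projected
    frame and the matched fraction.  A matched fraction below ``min_matched``
    raises — the cohort is probably mismatched.
    """
    reference_genes = list(reference_genes)
    if not reference_genes:
        raise ValueError("reference gene list is empty")
    present = [g for g in reference_genes if g in matrix.columns]
    frac = len(present) / len(reference_genes)
    if frac < min_matched:
        raise ValueError(
            f"only {frac:.1%} of reference genes matched "
            f"(floor {min_matched:.1%}); cohort likely mismatched")
    if reference_means is None:
        means = np.zeros(len(reference_genes))
    else:
        means = np.asarray(reference_means, dtype=np.float64)
    out = pd.DataFrame(
        np.tile(means, (matrix.shape[0], 1)),
        index=matrix.index, columns=reference_genes)
    out.loc[:, present] = matrix[present].to_numpy(dtype=np.float64)
    return out, frac


def make_cv_splits(sample_ids, k: int = 5, seed: int = 0) -> dict[str, int]:
    """Partition samples (cell lines) into k folds of near-equal size.

    Grouping is by sample, never by example: every example from a cell line
    shares that line's fold.  Deterministic given ``seed``.
    """
    unique = list(dict.fromkeys(sample_ids))
    if len(unique) < k:
        raise ValueError(f"need >= {k} distinct samples, got {len(unique)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    return {unique[j]: int(i % k) for i, j in enumerate(order)}


# ---------------------------------------------------------------------------
# File interfaces

def load_compound_table(path) -> list[CompoundRecord]:
    """CSV with columns compound_id, smiles, optional moa_class, targets
    (semicolon-separated gene symbols)."""
    df = pd.read_csv(path)
    records = []
    seen = set()
    for _, row in df.iterrows():
        cid = str(row["compound_id"])
        if cid in seen:
            raise ValueError(f"duplicate compound_id {cid!r}")
        seen.add(cid)
        targets = []
        if "targets" in df.columns and isinstance(row.get("targets"), str):
            targets = [t for t in row["targets"].split(";") if t]
        moa = row.get("moa_class")
        records.append(CompoundRecord(
            compound_id=cid, smiles=str(row["smiles"]),
            moa_class=None if pd.isna(moa) else str(moa),
            nominal_targets=targets))
    return records


def load_expression(path, genes_in_rows: bool = False, sep: str = "\t"
                    ) -> pd.DataFrame:
    """TSV/CSV expression table -> samples x genes frame."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if genes_in_rows:
        df = df.T
    if df.isna().any().any():
        raise ValueError("expression matrix contains missing values; "
                         "harmonize/impute first")
    return df.astype(np.float64)
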