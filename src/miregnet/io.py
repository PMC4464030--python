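"""Reading, writing and filtering of miRNA-target prediction data.

The central container is :class:`InteractionMatrix`, the weighted bipartite
adjacency matrix ``A`` whose entry ``A[mirna, gene]`` is the reliability
score (in ``[0, 1]``) of the candidate interaction.  Absent pairs score 0.
Prediction-score tables (one column per upstream prediction algorithm) and
validated-interaction lists travel as pandas DataFrames read from TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: value substituted for a missing upstream score after imputation.
#: Absence of a prediction is treated as evidence of non-interaction
#: for that algorithm.
MISSING_IMPUTE_DEFAULT = 0.0


# ---------------------------------------------------------------------------
# Prediction-score tables
# ---------------------------------------------------------------------------

def read_predictions(
    path: str | Path,
    algorithm_names: Sequence[str],
    missing_token: str = "NA",
) -> pd.DataFrame:
    """Read a TSV of per-pair upstream prediction scores.

    The file must have a header row with columns ``mirna``, ``gene`` and one
    column per entry of *algorithm_names*.  Cells equal to *missing_token*
    become ``NaN``; every other cell must parse as a finite float.

    Returns a DataFrame with columns ``mirna``, ``gene``, the score columns
    (float, ``NaN`` = missing) and ``validated`` (all ``False``), preserving
    file row order.

    Raises
    ------
    ValueError
        on a duplicate (mirna, gene) pair, a non-numeric score cell, a
        record whose scores are all missing, or missing columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["mirna", "gene", *algorithm_names]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing columns in {path}: {missing_cols}")
    df = df[required].copy()

    if (df["mirna"].str.len() == 0).any() or (df["gene"].str.len() == 0).any():
        raise ValueError("empty mirna or gene identifier")
    dup = df.duplicated(subset=["mirna", "gene"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(f"duplicate pair ({row['mirna']}, {row['gene']})")

    for col in algorithm_names:
        raw = df[col]
        is_missing = raw == missing_token
        parsed = pd.to_numeric(raw.where(~is_missing), errors="coerce")
        bad = parsed.isna() & ~is_missing
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(
                f"non-numeric score {raw[bad].iloc[0]!r} in column {col}, line {line}"
            )
        df[col] = parsed.astype(float)

    if len(df) and df[list(algorithm_names)].isna().all(axis=1).any():
        row = df[df[list(algorithm_names)].isna().all(axis=1)].iloc[0]
        raise ValueError(
            f"all scores missing for pair ({row['mirna']}, {row['gene']})"
        )
    df["validated"] = False
    return df.reset_index(drop=True)


def write_predictions(
    df: pd.DataFrame,
    path: str | Path,
    algorithm_names: Sequence[str],
    missing_token: str = "NA",
) -> None:
    """Write a prediction table back to TSV (inverse of :func:`read_predictions`)."""
    out = df[["mirna", "gene", *algorithm_names]].copy()
    out.to_csv(path, sep="\t", index=False, na_rep=missing_token)


def mark_validated(
    records: pd.DataFrame,
    validated_pairs: Iterable[tuple[str, str]],
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Flag records whose (mirna, gene) pair is experimentally validated.

    Returns the updated table and the list of validated pairs that match no
    record (reported rather than silently dropped).
    """
    pairs = set(map(tuple, validated_pairs))
    keys = list(zip(records["mirna"], records["gene"]))
    records = records.copy()
    records["validated"] = [k in pairs for k in keys]
    unmatched = sorted(pairs - set(keys))
    if unmatched:
        logger.warning("%d validated pairs not found among records", len(unmatched))
    return records, unmatched


def read_validated_pairs(path: str | Path) -> set[tuple[str, str]]:
    """Read a two-column (mirna, gene) TSV of validated interactions."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = list(df.columns[:2])
    return set(zip(df[cols[0]], df[cols[1]]))


def impute_missing(features: np.ndarray, value: float = MISSING_IMPUTE_DEFAULT) -> np.ndarray:
    """Replace NaN upstream scores by *value* (default 0)."""
    out = np.asarray(features, dtype=float).copy()
    out[np.isnan(out)] = value
    return out


# ---------------------------------------------------------------------------
# Interaction matrix
# ---------------------------------------------------------------------------

@dataclass
class InteractionMatrix:
    """Weighted bipartite miRNA x gene score matrix with scores in [0, 1].

    Indices are lexicographically sorted so every downstream computation is
    deterministic.  Internally dense (the scales this package targets are
    thousands of objects); absent pairs are stored as 0.
    """

    mirnas: tuple[str, ...]
    genes: tuple[str, ...]
    values: np.ndarray = field(repr=False)  # shape (n_mirna, n_gene)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.mirnas), len(self.genes)):
            raise ValueError("matrix shape does not match indices")
        if self.values.size and (
            np.nanmin(self.values) < 0 or np.nanmax(self.values) > 1
        ):
            raise ValueError("scores must lie in [0, 1]")
        self._mirna_pos = {m: i for i, m in enumerate(self.mirnas)}
        self._gene_pos = {g: j for j, g in enumerate(self.genes)}

    # -- construction -------------------------------------------------------

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str, float]]
    ) -> "InteractionMatrix":
        """Build a matrix from (mirna, gene, score) triples."""
        pairs = list(pairs)
        for m, g, s in pairs:
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"score {s} for ({m}, {g}) outside [0, 1]")
        mirnas = tuple(sorted({m for m, _, _ in pairs}))
        genes = tuple(sorted({g for _, g, _ in pairs}))
        values = np.zeros((len(mirnas), len(genes)))
        mp = {m: i for i, m in enumerate(mirnas)}
        gp = {g: j for j, g in enumerate(genes)}
        seen: set[tuple[str, str]] = set()
        for m, g, s in pairs:
            if (m, g) in seen:
                raise ValueError(f"duplicate pair ({m}, {g})")
            seen.add((m, g))
            values[mp[m], gp[g]] = s
        return cls(mirnas, genes, values)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "InteractionMatrix":
        """Read a three-column (mirna, gene, score) TSV."""
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        cols = list(df.columns[:3])
        return cls.from_pairs(
            zip(df[cols[0]], df[cols[1]], df[cols[2]].astype(float))
        )

    # -- access -------------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def score(self, mirna: str, gene: str) -> float:
        i = self._mirna_pos.get(mirna)
        j = self._gene_pos.get(gene)
        if i is None or j is None:
            return 0.0
        return float(self.values[i, j])

    def mirna_rows(self, mirnas: Iterable[str]) -> np.ndarray:
        return np.asarray(sorted(self._mirna_pos[m] for m in mirnas), dtype=int)

    def gene_cols(self, genes: Iterable[str]) -> np.ndarray:
        return np.asarray(sorted(self._gene_pos[g] for g in genes), dtype=int)

    def submatrix_mean(self, mirnas: Iterable[str], genes: Iterable[str]) -> float:
        """Mean score over the |mirnas| x |genes| block (absent cells count 0)."""
        rows = self.mirna_rows(mirnas)
        cols = self.gene_cols(genes)
        if rows.size == 0 or cols.size == 0:
            raise ValueError("empty bicluster dimension")
        return float(self.values[np.ix_(rows, cols)].mean())

    def entries(self) -> Iterator[tuple[str, str, float]]:
        """Iterate stored (nonzero) entries in lexicographic order."""
        for i, j in zip(*np.nonzero(self.values)):
            yield self.mirnas[i], self.genes[j], float(self.values[i, j])

    @property
    def n_entries(self) -> int:
        return int(np.count_nonzero(self.values))

    # -- transforms ---------------------------------------------------------

    def filter_by_score(self, threshold: float) -> "InteractionMatrix":
        """Keep entries with score >= *threshold*; indices unchanged."""
        vals = np.where(self.values >= threshold, self.values, 0.0)
        return InteractionMatrix(self.mirnas, self.genes, vals)

    def write_tsv(self, path: str | Path) -> None:
        rows = list(self.entries())
        pd.DataFrame(rows, columns=["mirna", "gene", "score"]).to_csv(
            path, sep="\t", index=False
        )
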