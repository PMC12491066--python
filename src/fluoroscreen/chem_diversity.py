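"""Tanimoto fingerprint similarity and diversity summaries for dye hits.

A screening campaign that merely rediscovers close analogues of known
amyloid reporters is of limited value, so hit lists are summarized by their
pairwise Tanimoto similarity -- |A intersect B| / |A union B| over binary
fingerprint bit sets -- both among themselves and against a reference
compound such as thioflavin T.  Low coefficients indicate a chemically
diverse hit list.

The module's contract begins at bit sets: fingerprint generation from
structures is delegated to an external toolkit (a helper wrapping RDKit
Morgan fingerprints is provided) because fingerprint type, radius and
length are an interface choice, not part of the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .plate_io import FormatError, ValidationError


@dataclass(frozen=True)
class Fingerprint:
    """A molecule's binary fingerprint as a set of set-bit indices."""

    molecule_id: str
    bits: frozenset[int]
    universe_size: int = 2048

    def __post_init__(self) -> None:
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.universe_size):
            raise ValidationError(
                f"{self.molecule_id}: bit indices outside [0, {self.universe_size})"
            )


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a & b| / |a | b| in [0, 1]."""
    if a.universe_size != b.universe_size:
        raise ValidationError(
            f"fingerprints {a.molecule_id!r} and {b.molecule_id!r} use different "
            f"bit universes ({a.universe_size} vs {b.universe_size})"
        )
    union = len(a.bits | b.bits)
    if union == 0:
        raise ValidationError(
            f"Tanimoto undefined: both {a.molecule_id!r} and {b.molecule_id!r} "
            f"are empty fingerprints"
        )
    return len(a.bits & b.bits) / union


@dataclass
class SimilaritySummary:
    """Pairwise similarities plus a histogram over the compared values."""

    matrix: pd.DataFrame | None  # symmetric, unit diagonal (None in reference mode)
    reference_similarities: pd.Series | None
    histogram_counts: np.ndarray
    bin_edges: np.ndarray

    @property
    def compared_values(self) -> np.ndarray:
        if self.reference_similarities is not None:
            return self.reference_similarities.to_numpy()
        m = self.matrix.to_numpy()
        iu = np.triu_indices_from(m, k=1)
        return m[iu]


def pairwise_similarity(
    fps: Sequence[Fingerprint],
    reference: Fingerprint | None = None,
    bin_width: float = 0.1,
) -> SimilaritySummary:
    """All-against-all (or all-against-reference) Tanimoto similarities.

    Without a reference, returns the symmetric n x n matrix with unit
    diagonal and a histogram over its n(n-1)/2 upper-triangle values.  With
    a reference (e.g. thioflavin T), the histogram covers the n reference
    comparisons instead.  Histogram bins tile [0, 1] with ``bin_width``;
    the last bin is right-closed so identity pairs are counted once.
    """
    if not fps:
        raise ValidationError("no fingerprints given")
    ids = [f.molecule_id for f in fps]
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if not np.isclose(edges[-1], 1.0):
        edges = np.append(edges, 1.0)
    if reference is not None:
        sims = pd.Series([tanimoto(f, reference) for f in fps], index=ids)
        counts, _ = np.histogram(sims.to_numpy(), bins=edges)
        return SimilaritySummary(None, sims, counts, edges)
    if len(fps) < 2:
        raise ValidationError("need >= 2 fingerprints (or one plus a reference)")
    n = len(fps)
    m = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = tanimoto(fps[i], fps[j])
    matrix = pd.DataFrame(m, index=ids, columns=ids)
    values = m[np.triu_indices(n, k=1)]
    counts, _ = np.histogram(values, bins=edges)
    return SimilaritySummary(matrix, None, counts, edges)


# ---------------------------------------------------------------------------
# Fingerprint file interchange
# ---------------------------------------------------------------------------

FP_COLUMNS = ("molecule_id", "universe_size", "bits")


def read_fingerprints_csv(path: str | Path) -> list[Fingerprint]:
    """Read fingerprints from CSV: molecule_id, universe_size, ';'-joined bit indices.

    An optional ``smiles`` column is passed through untouched (available via
    the returned frame of :func:`pd.read_csv` if callers need it); empty bit
    fields give empty fingerprints, which are legal but flagged.
    """
    df = pd.read_csv(Path(path))
    for col in FP_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    fps: list[Fingerprint] = []
    for _, row in df.iterrows():
        raw = row["bits"]
        if pd.isna(raw) or str(raw).strip() == "":
            bits: frozenset[int] = frozenset()
        else:
            bits = frozenset(int(tok) for tok in str(raw).split(";"))
        fps.append(Fingerprint(str(row["molecule_id"]), bits, int(row["universe_size"])))
    return fps


def write_fingerprints_csv(fps: Sequence[Fingerprint], path: str | Path) -> None:
    records = [
        {
            "molecule_id": f.molecule_id,
            "universe_size": f.universe_size,
            "bits": ";".join(str(b) for b in sorted(f.bits)),
        }
        for f in fps
    ]
    pd.DataFrame.from_records(records, columns=list(FP_COLUMNS)).to_csv(
        Path(path), index=False, lineterminator="\n"
    )


def fingerprint_from_smiles(
    molecule_id: str,
    smiles: str,
    radius: int = 2,
    n_bits: int = 2048,
) -> Fingerprint:
    """Morgan (circular) fingerprint of a SMILES string via RDKit.

    Convenience wrapper at the interface boundary; the similarity statistics
    themselves operate purely on bit sets.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"{molecule_id}: unparseable SMILES {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return Fingerprint(molecule_id, frozenset(fp.GetOnBits()), n_bits)
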