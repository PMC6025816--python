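"""Kimura 2-parameter pairwise distances and the per-region matrix.

The K2P model corrects observed divergence for multiple hits while
distinguishing transitions (A<->G, C<->T; proportion P) from
transversions (all other mismatches; proportion Q):

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

Columns where either sequence has a gap or N are excluded per pair
(pairwise deletion).  When the log arguments are non-positive the
distance is undefined (saturation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .records import RegionAlignment

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class SaturationError(ValueError):
    """Divergence too high for the K2P correction (log argument <= 0)."""


class NoOverlapError(ValueError):
    """Two sequences share no column with unambiguous bases in both."""


@dataclass(frozen=True)
class PairwiseComparison:
    """Shared-site count, transition/transversion proportions and distance."""

    sites_compared: int
    P: float
    Q: float
    d: float


def k2p_distance(a: str, b: str) -> PairwiseComparison:
    """K2P distance between two rows of one alignment.

    Parameters
    ----------
    a, b : str
        Aligned sequences of equal length over {A,C,G,T,N,-}.

    Raises
    ------
    NoOverlapError
        If no column has unambiguous bases in both sequences.
    SaturationError
        If 1-2P-Q <= 0 or 1-2Q <= 0.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x in "N-" or y in "N-":
            continue
        n += 1
        if x == y:
            continue
        if (x, y) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise NoOverlapError("no shared unambiguous columns")
    P = ts / n
    Q = tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P undefined at P={P:.4f}, Q={Q:.4f} (saturated)"
        )
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return PairwiseComparison(sites_compared=n, P=P, Q=Q, d=d)


class DistanceMatrix:
    """Symmetric K2P distance matrix over the samples of one region.

    ``values`` is a dense float array with zero diagonal; NaN marks a
    dropped (saturated/no-overlap) pair under the ``drop-pair`` policy.
    """

    def __init__(self, sample_ids, species_of, values):
        self.sample_ids = list(sample_ids)
        self.species_of = dict(species_of)
        self.values = np.asarray(values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("values shape does not match sample_ids")
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    def __len__(self) -> int:
        return len(self.sample_ids)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    @property
    def species(self) -> list[str]:
        """Distinct species, sorted."""
        return sorted(set(self.species_of.values()))

    def samples_of(self, species: str) -> list[str]:
        return [s for s in self.sample_ids if self.species_of[s] == species]

    def pairs(self):
        """Yield (id_a, id_b, distance) over defined unordered pairs."""
        n = len(self.sample_ids)
        for i in range(n):
            for j in range(i + 1, n):
                v = self.values[i, j]
                if not np.isnan(v):
                    yield self.sample_ids[i], self.sample_ids[j], float(v)

    def drop(self, sample_ids) -> "DistanceMatrix":
        """Matrix restricted to samples NOT in ``sample_ids``."""
        gone = set(sample_ids)
        keep = [i for i, s in enumerate(self.sample_ids) if s not in gone]
        ids = [self.sample_ids[i] for i in keep]
        return DistanceMatrix(
            ids,
            {s: self.species_of[s] for s in ids},
            self.values[np.ix_(keep, keep)],
        )

    def to_phylip(self) -> str:
        """Square PHYLIP-style matrix (label + tab-separated row)."""
        lines = [str(len(self.sample_ids))]
        for i, s in enumerate(self.sample_ids):
            row = "\t".join(f"{v:.8f}" for v in self.values[i])
            lines.append(f"{s}\t{row}")
        return "\n".join(lines) + "\n"


# byte codes for vectorised comparison: A=0, C=1, G=2, T=3 (so partner
# under a transition is code ^ 2), anything else = missing
_ENC = np.full(256, 255, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _ENC[_b] = _c


def _all_pair_counts(seqs: list[str]):
    """(shared sites, transitions, transversions) for every pair, via
    broadcast comparison of the encoded alignment."""
    arr = _ENC[
        np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    ]
    valid = arr != 255
    both = valid[:, None, :] & valid[None, :, :]
    x = arr[:, None, :]
    y = arr[None, :, :]
    diff = (x != y) & both
    ts = diff & ((x ^ y) == 2)
    return (
        both.sum(axis=2).astype(float),
        ts.sum(axis=2).astype(float),
        (diff & ~ts).sum(axis=2).astype(float),
    )


def distance_matrix(
    aln: RegionAlignment, on_undefined: str = "error", cap: float = 1.0
) -> DistanceMatrix:
    """All-pairs K2P matrix for one region alignment.

    ``on_undefined`` controls saturated / no-overlap pairs:
    ``error`` raises, ``drop-pair`` stores NaN with a warning, ``cap``
    stores the ``cap`` value.
    """
    if on_undefined not in ("error", "drop-pair", "cap"):
        raise ValueError(f"unknown policy {on_undefined!r}")
    n_sites, ts, tv = _all_pair_counts([r.sequence for r in aln.records])
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(n_sites > 0, ts / n_sites, np.nan)
        Q = np.where(n_sites > 0, tv / n_sites, np.nan)
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        vals = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    undefined = (n_sites == 0) | (w1 <= 0) | (w2 <= 0)
    np.fill_diagonal(undefined, False)
    np.fill_diagonal(vals, 0.0)
    if undefined.any():
        ii, jj = np.nonzero(np.triu(undefined, 1))
        pairs = [(aln.records[i].sample_id, aln.records[j].sample_id) for i, j in zip(ii, jj)]
        if on_undefined == "error":
            a, b = pairs[0]
            # re-raise with the scalar path's specific error
            k2p_distance(
                aln.records[int(ii[0])].sequence, aln.records[int(jj[0])].sequence
            )
            raise SaturationError(f"pair ({a}, {b}) undefined")  # pragma: no cover
        if on_undefined == "drop-pair":
            warnings.warn(
                f"{aln.region}: dropped {len(pairs)} undefined pair(s), e.g. {pairs[0]}"
            )
            vals[undefined] = np.nan
        else:
            vals[undefined] = cap
    return DistanceMatrix(aln.sample_ids, aln.species_of, vals)
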