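"""Sequence encodings for site-centered windows.

Two feature spaces are supported:

* **chemical** — each nucleotide maps to a 3-bit code describing its ring
  structure (purine vs pyrimidine), hydrogen-bond strength (weak vs strong)
  and functional group (amino vs keto): A -> (1,1,1), C -> (0,0,1),
  G -> (1,0,0), T -> (0,1,0).  A length-L window becomes a binary vector of
  length 3L.
* **CNF** (cumulative nucleotide frequency) — position i (1-based) carries the
  frequency of the nucleotide occupying it within the prefix of length i,
  i.e. count(seq[i] in seq[1..i]) / i.  The first entry is always 1 and every
  entry lies in (0, 1]; unlike the per-base chemical code this encoding is
  context sensitive.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import SiteRecord

CHEMICAL_CODE = {
    "A": (1, 1, 1),
    "C": (0, 0, 1),
    "G": (1, 0, 0),
    "T": (0, 1, 0),
}
_CODE_TO_BASE = {v: k for k, v in CHEMICAL_CODE.items()}
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _prepare(seq: str, u_to_t: bool = False) -> str:
    if not seq:
        raise ValidationError("cannot encode an empty sequence")
    seq = seq.upper()
    if u_to_t:
        seq = seq.replace("U", "T")
    for pos, base in enumerate(seq, start=1):
        if base not in _BASE_INDEX:
            raise ValidationError(
                f"invalid character {base!r} at position {pos} (alphabet is ACGT)"
            )
    return seq


def encode_chemical(seq: str, u_to_t: bool = False) -> np.ndarray:
    """Encode a sequence as the concatenation of per-base 3-bit chemical codes."""
    seq = _prepare(seq, u_to_t)
    out = np.empty(3 * len(seq), dtype=np.uint8)
    for i, base in enumerate(seq):
        out[3 * i : 3 * i + 3] = CHEMICAL_CODE[base]
    return out


def decode_chemical(bits: Sequence[int]) -> str:
    """Invert :func:`encode_chemical` (the per-position code is injective)."""
    bits = np.asarray(bits, dtype=int)
    if bits.ndim != 1 or bits.size % 3:
        raise ValidationError("chemical bit vector length must be a multiple of 3")
    bases = []
    for i in range(0, bits.size, 3):
        triple = tuple(int(b) for b in bits[i : i + 3])
        if triple not in _CODE_TO_BASE:
            raise ValidationError(f"invalid chemical code {triple} at base {i // 3 + 1}")
        bases.append(_CODE_TO_BASE[triple])
    return "".join(bases)


def encode_cnf(seq: str, u_to_t: bool = False) -> np.ndarray:
    """Cumulative nucleotide frequency vector of a sequence.

    ``out[i-1]`` (1-based position i) is the number of occurrences of
    ``seq[i]`` among the first i characters, divided by i.
    """
    seq = _prepare(seq, u_to_t)
    idx = np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.intp, count=len(seq))
    onehot = np.zeros((len(seq), 4))
    onehot[np.arange(len(seq)), idx] = 1.0
    cum = onehot.cumsum(axis=0)
    positions = np.arange(1, len(seq) + 1, dtype=float)
    return cum[np.arange(len(seq)), idx] / positions


def encode_all(
    records: Iterable[SiteRecord],
    which: str = "cnf",
    u_to_t: bool = False,
) -> pd.DataFrame:
    """Encode every record's reference sequence; one row per record, order preserved.

    ``which`` selects the feature space (``"chemical"`` or ``"cnf"``).
    Per-record encoding errors are re-raised with the offending site_id.
    """
    encoders = {"chemical": encode_chemical, "cnf": encode_cnf}
    if which not in encoders:
        raise ValidationError(f"unknown feature space {which!r}")
    rows, ids = [], []
    for rec in records:
        try:
            rows.append(encoders[which](rec.ref_seq, u_to_t))
        except ValidationError as exc:
            raise ValidationError(f"site {rec.site_id!r}: {exc}") from exc
        ids.append(rec.site_id)
    if not rows:
        return pd.DataFrame(index=pd.Index([], name="site_id"))
    frame = pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="site_id"))
    frame.columns = [f"{which}_{i}" for i in range(frame.shape[1])]
    return frame
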