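"""Sequence preparation: alphabet normalization, fixed-length segmentation
with overlap, one-hot / 4-mer encodings, color-platelet images, and SMOTE.

Segments default to 3000 nt with 50% overlap.  Short tails are completed
with a dedicated PAD symbol that one-hot encodes to an all-zero row and is
excluded from k-mer tokens, so padding injects no composition signal.
Ambiguity codes (N, R, Y, ...) also map to PAD: deterministic and
signal-neutral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

#: padding / ambiguity placeholder; never counted as sequence signal
PAD = "-"

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

_NORMALIZE = str.maketrans(
    {c: c for c in _BASES} | {"U": "T"} | {c: PAD for c in "NRYSWKMBDHV" + PAD}
)


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class Segment:
    """A fixed-length window of a source sequence.

    ``offset`` is the 0-based start in the source; ``pad_length`` counts
    trailing PAD symbols appended to reach the window length.
    """

    source_id: str
    offset: int
    bases: str
    pad_length: int

    def __post_init__(self) -> None:
        if self.pad_length >= len(self.bases):
            raise ValidationError("pad_length must be smaller than the segment length")
        if self.pad_length and set(self.bases[-self.pad_length :]) != {PAD}:
            raise ValidationError("PAD must appear only as a suffix")


@dataclass(frozen=True)
class KmerSentence:
    """Tokenized k-mers of a segment with their 1-based lexicographic ranks."""

    tokens: tuple[str, ...]
    indices: tuple[int, ...]
    k: int

    def __len__(self) -> int:
        return len(self.tokens)


def normalize_alphabet(seq: str) -> str:
    """Uppercase, map U->T, and map anything outside {A,C,G,T} to PAD."""
    if not seq:
        raise ValidationError("empty sequence")
    out = seq.upper().translate(_NORMALIZE)
    # anything still unknown (digits, gaps, etc.) becomes PAD as well
    return "".join(c if c in _BASES or c == PAD else PAD for c in out)


def segment_sequence(seq: str, source_id: str = "", L: int = 3000, overlap: float = 0.5) -> list[Segment]:
    """Split a normalized sequence into windows of length L with the given overlap.

    Windows start at 0, stride, 2*stride, ... with stride = round(L*(1-overlap));
    a new window opens only while the previous one ends before the sequence
    does, and the final window is PAD-completed.  Every base is covered by at
    least one window.
    """
    if not 0 <= overlap < 1:
        raise ValidationError("overlap must lie in [0, 1)")
    if L < 2:
        raise ValidationError("segment length must be >= 2")
    stride = int(round(L * (1.0 - overlap)))
    if stride < 1:
        raise ValidationError("overlap too close to 1: stride rounds to 0")
    offsets = [0]
    while offsets[-1] + L < len(seq):
        offsets.append(offsets[-1] + stride)
    segments = []
    for off in offsets:
        window = seq[off : off + L]
        pad = L - len(window)
        segments.append(Segment(source_id, off, window + PAD * pad, pad))
    return segments


def one_hot_encode(segment: Segment | str) -> np.ndarray:
    """Encode a segment as an (L, 4) matrix, channels A,C,G,T; PAD rows are zero."""
    bases = segment.bases if isinstance(segment, Segment) else segment
    mat = np.zeros((len(bases), 4), dtype=np.float32)
    for i, c in enumerate(bases):
        if c == PAD:
            continue
        j = _BASE_INDEX.get(c)
        if j is None:
            raise ValidationError(f"unnormalized symbol {c!r} at position {i}")
        mat[i, j] = 1.0
    return mat


def one_hot_decode(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`; all-zero rows decode to PAD."""
    out = []
    for row in np.asarray(matrix):
        if row.sum() == 0:
            out.append(PAD)
        else:
            out.append(_BASES[int(np.argmax(row))])
    return "".join(out)


def kmer_index(token: str) -> int:
    """1-based lexicographic rank of a k-mer over A<C<G<T (AAAA->1, AAAC->2...)."""
    rank = 0
    for c in token:
        rank = rank * 4 + _BASE_INDEX[c]
    return rank + 1


def kmer_tokenize(segment: Segment | str, k: int = 4, stride: int = 1) -> KmerSentence:
    """Slide a length-k window over the segment; tokens containing PAD are skipped."""
    if k < 1 or stride < 1:
        raise ValidationError("k and stride must be >= 1")
    bases = segment.bases if isinstance(segment, Segment) else segment
    tokens = []
    for i in range(0, len(bases) - k + 1, stride):
        tok = bases[i : i + k]
        if PAD in tok:
            continue
        tokens.append(tok)
    if not tokens:
        warnings.warn("segment shorter than k after PAD removal: empty sentence")
    return KmerSentence(tuple(tokens), tuple(kmer_index(t) for t in tokens), k)


def palette_color(index: int) -> tuple[int, int, int]:
    """Fixed bijective palette over the 256 4-mers: i -> (i, 85i mod 256, 171i mod 256)."""
    i = (index - 1) % 256
    return (i, (i * 85) % 256, (i * 171) % 256)


def render_kmer_image(sentence: KmerSentence, width: int):
    """Render a k-mer sentence as an RGB color-platelet image.

    Tokens are laid out row-major into ``width`` columns; each distinct
    4-mer index maps to a distinct fixed palette color; trailing cells
    are black.  Returns a ``PIL.Image``.
    """
    from PIL import Image

    if width <= 0:
        raise ValidationError("width must be positive")
    n = len(sentence)
    if n == 0:
        warnings.warn("empty sentence: rendering an all-black 1-row image")
        return Image.fromarray(np.zeros((1, width, 3), dtype=np.uint8))
    rows = -(-n // width)
    arr = np.zeros((rows * width, 3), dtype=np.uint8)
    for t, idx in enumerate(sentence.indices):
        arr[t] = palette_color(idx)
    return Image.fromarray(arr.reshape(rows, width, 3))


def smote_oversample(
    X: np.ndarray, labels, k_neighbors: int = 5, seed: int = 0,
    return_indices: bool = False,
):
    """Equalize class counts by synthesizing minority points.

    Each synthetic point is ``x + lam * (x_nn - x)`` with ``lam ~ U[0,1]``
    and ``x_nn`` one of the ``k_neighbors`` same-class Euclidean nearest
    neighbors of the seed instance ``x``.  After oversampling every class
    count equals the majority count.

    With ``return_indices`` a third array maps every output row to the
    original row it was seeded from (originals map to themselves), so
    auxiliary per-instance labels can be propagated.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    counts = pd.Series(labels).value_counts()
    majority = int(counts.max())
    new_X = [X]
    new_y = [labels]
    origin = [np.arange(len(X))]
    for cls, cnt in counts.items():
        need = majority - int(cnt)
        if need == 0:
            continue
        if cnt < 2:
            raise ValidationError(f"class {cls!r} has fewer than 2 members; SMOTE undefined")
        member_idx = np.flatnonzero(labels == cls)
        members = X[member_idx]
        k = min(k_neighbors, len(members) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(members)
        _, nbr = nn.kneighbors(members)  # column 0 is the point itself
        seeds = rng.integers(0, len(members), size=need)
        picks = rng.integers(1, k + 1, size=need)
        lam = rng.random(need)
        x = members[seeds]
        x_nn = members[nbr[seeds, picks]]
        new_X.append(x + lam[:, None] * (x_nn - x))
        new_y.append(np.full(need, cls, dtype=labels.dtype))
        origin.append(member_idx[seeds])
    out = (np.concatenate(new_X, axis=0), np.concatenate(new_y, axis=0))
    if return_indices:
        return out + (np.concatenate(origin),)
    return out


def segment_manifest(segments: list[Segment]) -> pd.DataFrame:
    """Tabulate segment provenance as source_id / offset / pad_length."""
    return pd.DataFrame(
        [(s.source_id, s.offset, s.pad_length) for s in segments],
        columns=["source_id", "offset", "pad_length"],
    )
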