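"""Skip-gram k-mer embedding over the full 4^k vocabulary.

For each position t in a k-mer sentence, the focus token predicts its
context tokens at offsets {-w..-1, +1..+w} through a linear layer and a
full softmax over the vocabulary (V = 256 for k = 4, so negative sampling
or a hierarchical softmax would buy nothing).  Because the loss is a sum
over (focus, context) pairs, training operates on the aggregated
co-occurrence count matrix, which makes full-batch gradients exact and
cheap regardless of corpus size.

The per-sentence focus/context relationship matrices mirror the same
windowed neighborhoods and are retained for inspection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from taxonembed.nn import Adam, Param
from taxonembed.seq_prep import KmerSentence, ValidationError


def full_vocabulary(k: int) -> dict[str, int]:
    """Token -> 0-based index over all 4^k k-mers, lexicographic A<C<G<T."""
    return {"".join(t): i for i, t in enumerate(product("ACGT", repeat=k))}


def softmax_rows(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass(frozen=True)
class RelationshipMatrix:
    """Per-position focus one-hots and windowed context counts, concatenated."""

    focus: np.ndarray  # (T, V), one-hot rows
    context: np.ndarray  # (T, V), counts of tokens within the window
    w: int

    @property
    def combined(self) -> np.ndarray:
        return np.concatenate([self.focus, self.context], axis=1)


def build_focus_context(sentence: KmerSentence, w: int = 1) -> RelationshipMatrix:
    """Build the focus and context matrices for one sentence.

    The context of position t is positions {t-w..t-1, t+1..t+w} clipped to
    the sentence, so boundary rows have truncated context counts.
    """
    if w < 1:
        raise ValidationError("context window w must be >= 1")
    big_t = len(sentence)
    if big_t == 0:
        raise ValidationError("empty sentence")
    vocab_size = 4**sentence.k
    idx = np.asarray(sentence.indices) - 1
    focus = np.zeros((big_t, vocab_size))
    focus[np.arange(big_t), idx] = 1.0
    context = np.zeros((big_t, vocab_size))
    for off in range(1, w + 1):
        if off >= big_t:
            break
        np.add.at(context, (np.arange(off, big_t), idx[:-off]), 1.0)  # left neighbor
        np.add.at(context, (np.arange(big_t - off), idx[off:]), 1.0)  # right neighbor
    return RelationshipMatrix(focus, context, w)


@dataclass
class EmbeddingModel:
    """Trained skip-gram embedding: dense vectors for every k-mer."""

    vocabulary: dict[str, int]
    input_weights: np.ndarray  # (V, d)
    output_weights: np.ndarray  # (d, V)
    d: int
    w: int
    k: int
    loss_history: list[float] = field(default_factory=list)

    def vector(self, token: str) -> np.ndarray:
        if token not in self.vocabulary:
            raise KeyError(f"token {token!r} not in vocabulary")
        return self.input_weights[self.vocabulary[token]]

    def save(self, prefix: str) -> None:
        np.savez(prefix + ".npz", input_weights=self.input_weights,
                 output_weights=self.output_weights)
        with open(prefix + ".json", "w") as fh:
            json.dump({"vocabulary": self.vocabulary, "d": self.d, "w": self.w,
                       "k": self.k, "loss_history": self.loss_history}, fh)

    @classmethod
    def load(cls, prefix: str) -> "EmbeddingModel":
        arrays = np.load(prefix + ".npz")
        with open(prefix + ".json") as fh:
            meta = json.load(fh)
        return cls(meta["vocabulary"], arrays["input_weights"], arrays["output_weights"],
                   meta["d"], meta["w"], meta["k"], meta["loss_history"])


def cooccurrence_counts(sentences: list[KmerSentence], w: int, vocab_size: int) -> np.ndarray:
    """Aggregate (focus, context) pair counts over a corpus."""
    counts = np.zeros((vocab_size, vocab_size))
    for sent in sentences:
        idx = np.asarray(sent.indices) - 1
        for off in range(1, w + 1):
            if off >= len(idx):
                break
            np.add.at(counts, (idx[off:], idx[:-off]), 1.0)
            np.add.at(counts, (idx[:-off], idx[off:]), 1.0)
    return counts


def train_embedding(
    sentences: list[KmerSentence],
    d: int = 32,
    w: int = 1,
    epochs: int = 150,
    learning_rate: float = 0.05,
    seed: int = 0,
) -> EmbeddingModel:
    """Train the skip-gram embedding with a full softmax output layer.

    One epoch is one exact full-batch Adam step on the pair-count
    weighted cross-entropy; the mean per-pair loss is recorded per epoch.
    """
    if not sentences:
        raise ValidationError("empty corpus")
    k = sentences[0].k
    vocab = full_vocabulary(k)
    vocab_size = len(vocab)
    if d >= vocab_size:
        import warnings

        warnings.warn(f"embedding dim {d} >= vocabulary size {vocab_size}: not compressive")
    counts = cooccurrence_counts(sentences, w, vocab_size)
    total = counts.sum()
    if total == 0:
        raise ValidationError("corpus has no (focus, context) pairs")
    rng = np.random.default_rng(seed)
    win = Param(rng.normal(0.0, 0.1, size=(vocab_size, d)))
    wout = Param(rng.normal(0.0, 0.1, size=(d, vocab_size)))
    opt = Adam([win, wout], lr=learning_rate)
    row_n = counts.sum(axis=1)
    history = []
    for _ in range(epochs):
        logits = win.value @ wout.value
        logz = logits - logits.max(axis=1, keepdims=True)
        logp = logz - np.log(np.exp(logz).sum(axis=1, keepdims=True))
        loss = -(counts * logp).sum() / total
        history.append(float(loss))
        probs = np.exp(logp)
        dlogits = (probs * row_n[:, None] - counts) / total
        opt.zero_grad()
        win.grad += dlogits @ wout.value.T
        wout.grad += win.value.T @ dlogits
        opt.step()
    return EmbeddingModel(vocab, win.value, wout.value, d, w, k, history)


def plot_embedding_scatter(model: EmbeddingModel, path: str) -> None:
    """Scatter the first two embedding coordinates of every k-mer.

    Intended for visual inspection of clustering (train with d=2 for a
    faithful picture); no quantitative claims attach to the plot.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xy = model.input_weights[:, :2]
    fig, ax = plt.subplots(figsize=(7, 7))
    ax.scatter(xy[:, 0], xy[:, 1], s=6, alpha=0.6)
    for token, i in model.vocabulary.items():
        if i % 16 == 0:  # annotate a readable subset
            ax.annotate(token, xy[i], fontsize=6, alpha=0.7)
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    ax.set_title(f"{len(model.vocabulary)}-token {model.k}-mer embedding")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def embed_sentence(model: EmbeddingModel, sentence: KmerSentence) -> np.ndarray:
    """Map a sentence to its (T, d) dense matrix of embedding rows."""
    rows = []
    for tok in sentence.tokens:
        if tok not in model.vocabulary:
            raise KeyError(f"token {tok!r} not in vocabulary")
        rows.append(model.vocabulary[tok])
    if not rows:
        return np.zeros((0, model.d))
    return model.input_weights[np.asarray(rows)]
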