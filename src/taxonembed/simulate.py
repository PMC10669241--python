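"""Synthetic taxonomy-structured sequence corpora.

Generates FASTA corpora whose labels form a three-level tree
(host -> family -> clade) with planted nucleotide motifs supplying a
controllable amount of composition signal at each level.  Background
bases are i.i.d. uniform over {A,C,G,T}; each sequence carries a
configurable fraction of motif-covered positions, split between its
clade motif and the shared family/host ancestor motifs, with optional
per-base substitution noise inside planted motifs.

The default host proportions emulate a skewed four-host viral corpus
(13.5% plant, 20.6% fungi, 29.7% human, 36.3% bacteria).
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = np.array(list("ACGT"))

#: canonical host order used throughout the package
DEFAULT_HOSTS = ("bacteria", "fungi", "human", "plant")

#: empirical host proportions the generator emulates, in DEFAULT_HOSTS order
DEFAULT_HOST_PROPORTIONS = (0.363, 0.206, 0.297, 0.135)


class ConfigurationError(ValueError):
    """Raised for invalid simulation settings."""


@dataclass(frozen=True)
class TaxonomyTree:
    """A host -> family -> clade label hierarchy with node motifs.

    ``motif_table`` maps every node name (host, family or clade) to the
    nucleotide motif planted for that node; sibling motifs are pairwise
    distinct so that each level carries a discriminable signal.
    """

    hosts: tuple[str, ...]
    families_per_host: int
    clades_per_family: int
    motif_table: Mapping[str, str]

    @property
    def families(self) -> list[str]:
        return [f"{h}_f{i}" for h in self.hosts for i in range(1, self.families_per_host + 1)]

    @property
    def clades(self) -> list[str]:
        return [f"{f}_c{j}" for f in self.families for j in range(1, self.clades_per_family + 1)]

    def family_of(self, clade: str) -> str:
        return clade.rsplit("_c", 1)[0]

    def host_of(self, family_or_clade: str) -> str:
        return family_or_clade.split("_f", 1)[0]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic corpus."""

    n_sequences: int = 200
    length_range: tuple[int, int] = (1000, 9000)
    host_proportions: tuple[float, float, float, float] = DEFAULT_HOST_PROPORTIONS
    motif_length: int = 12
    motif_density: float = 0.5
    mutation_rate: float = 0.0
    seed: int = 0
    #: fraction of planted sites carrying the clade / family / host motif
    ancestor_mix: tuple[float, float, float] = (0.6, 0.2, 0.2)
    rna: bool = False

    def __post_init__(self) -> None:
        if self.length_range[0] < 8:
            raise ConfigurationError("length_range minimum must be >= 8")
        if self.length_range[0] > self.length_range[1]:
            raise ConfigurationError("length_range must be (min, max) with min <= max")
        if not 0.0 <= self.motif_density <= 1.0:
            raise ConfigurationError("motif_density must lie in [0, 1]")
        if not 0.0 <= self.mutation_rate <= 0.5:
            raise ConfigurationError("mutation_rate must lie in [0, 0.5]")
        props = np.asarray(self.host_proportions, dtype=float)
        # the emulated corpus percentages round to a 100.1% total, so allow
        # rounding slack; proportions are renormalized when drawing
        if props.min() < 0 or abs(props.sum() - 1.0) > 1e-2:
            raise ConfigurationError("host_proportions must be non-negative and sum to 1")


def _draw_distinct_motifs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Draw n pairwise-distinct motif strings of the given length."""
    if length >= 4 and 4**min(length, 16) < n:
        raise ConfigurationError(f"cannot draw {n} distinct motifs of length {length}")
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        motif = "".join(ALPHABET[rng.integers(0, 4, size=length)])
        if motif not in seen:
            seen.add(motif)
            out.append(motif)
    return out


def generate_taxonomy(
    hosts: Sequence[str] = DEFAULT_HOSTS,
    families_per_host: int = 2,
    clades_per_family: int = 2,
    motif_length: int = 12,
    seed: int = 0,
) -> TaxonomyTree:
    """Build a deterministic host/family/clade tree with distinct node motifs.

    Motifs are drawn without replacement across the whole tree, which
    makes every sibling set pairwise distinct a fortiori.
    """
    hosts = tuple(hosts)
    if len(set(hosts)) != len(hosts):
        raise ConfigurationError(f"duplicate host names: {sorted(hosts)}")
    if families_per_host < 1 or clades_per_family < 1:
        raise ConfigurationError("families_per_host and clades_per_family must be >= 1")
    if motif_length < 4:
        raise ConfigurationError("motif_length must be >= 4")
    rng = np.random.default_rng(seed)
    tree = TaxonomyTree(hosts, families_per_host, clades_per_family, {})
    nodes = list(hosts) + tree.families + tree.clades
    motifs = _draw_distinct_motifs(rng, len(nodes), motif_length)
    table = dict(zip(nodes, motifs))
    return dataclasses.replace(tree, motif_table=table)


def _mutate(rng: np.random.Generator, motif: np.ndarray, rate: float) -> np.ndarray:
    if rate == 0.0:
        return motif
    hit = rng.random(motif.size) < rate
    if hit.any():
        motif = motif.copy()
        # substitute with one of the three other bases
        cur = np.searchsorted(ALPHABET, motif[hit])
        shift = rng.integers(1, 4, size=hit.sum())
        motif[hit] = ALPHABET[(cur + shift) % 4]
    return motif


def _simulate_sequence(
    rng: np.random.Generator, clade: str, tree: TaxonomyTree, config: SimulationConfig
) -> str:
    length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
    bases = ALPHABET[rng.integers(0, 4, size=length)]
    m = config.motif_length
    n_slots = length // m
    n_plant = int(round(config.motif_density * length / m))
    n_plant = min(n_plant, n_slots)
    if n_plant > 0:
        # non-overlapping sites: sample aligned slots, then jitter is not
        # needed for composition signal
        slots = rng.choice(n_slots, size=n_plant, replace=False)
        family = tree.family_of(clade)
        host = tree.host_of(clade)
        levels = [clade, family, host]
        mix = np.asarray(config.ancestor_mix, dtype=float)
        mix = mix / mix.sum()
        which = rng.choice(3, size=n_plant, p=mix)
        for slot, lvl in zip(slots, which):
            motif = np.array(list(tree.motif_table[levels[lvl]]))
            motif = _mutate(rng, motif, config.mutation_rate)
            bases[slot * m : slot * m + m] = motif
    seq = "".join(bases)
    if config.rna:
        seq = seq.replace("T", "U")
    return seq


class EmptyCorpusError(ValueError):
    """Raised when a corpus with zero sequences is requested."""


def generate_corpus(
    tree: TaxonomyTree, config: SimulationConfig
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Generate FASTA records and their host/family/clade label table.

    Returns Biopython ``SeqRecord`` objects (ids ``seq0000``...) and a
    DataFrame with columns ``id``, ``host``, ``family``, ``clade`` in
    record order.  Deterministic for a fixed ``config.seed``.
    """
    if config.n_sequences < 1:
        raise EmptyCorpusError("n_sequences must be >= 1")
    if len(config.host_proportions) != len(tree.hosts):
        raise ConfigurationError("host_proportions length must match number of hosts")
    rng = np.random.default_rng(config.seed)
    props = np.asarray(config.host_proportions, dtype=float)
    props = props / props.sum()
    host_idx = rng.choice(len(tree.hosts), size=config.n_sequences, p=props)
    records: list[SeqRecord] = []
    rows: list[dict[str, str]] = []
    for i, hi in enumerate(host_idx):
        host = tree.hosts[hi]
        fam = f"{host}_f{rng.integers(1, tree.families_per_host + 1)}"
        clade = f"{fam}_c{rng.integers(1, tree.clades_per_family + 1)}"
        seq = _simulate_sequence(rng, clade, tree, config)
        rid = f"seq{i:04d}"
        records.append(SeqRecord(Seq(seq), id=rid, description=""))
        rows.append({"id": rid, "host": host, "family": fam, "clade": clade})
    return records, pd.DataFrame(rows)


def write_corpus(records: list[SeqRecord], labels: pd.DataFrame, out_dir: str) -> tuple[str, str]:
    """Write records as multi-line FASTA and labels as a TSV; returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    fasta = os.path.join(out_dir, "corpus.fasta")
    tsv = os.path.join(out_dir, "labels.tsv")
    SeqIO.write(records, fasta, "fasta")
    labels.to_csv(tsv, sep="\t", index=False)
    return fasta, tsv


def read_corpus(fasta_path: str, labels_path: str) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Read a FASTA + label-table pair, checking that ids are in bijection."""
    records = list(SeqIO.parse(fasta_path, "fasta"))
    labels = pd.read_csv(labels_path, sep="\t", dtype=str)
    rec_ids = {r.id for r in records}
    lab_ids = set(labels["id"])
    if rec_ids != lab_ids:
        missing = rec_ids.symmetric_difference(lab_ids)
        raise ValueError(f"FASTA ids and label table disagree on {len(missing)} ids")
    return records, labels
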