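"""Synthetic labeled data generators.

Two kinds of data are produced, matching what the binning method assumes
about real metagenomes:

* **Species models** — order-``r`` Markov chains over {A, C, G, T} whose
  transition rows are Dirichlet perturbations of a GC-targeted base
  distribution.  Each model plays the role of one bacterial species: it has
  a distinct compositional "texture" (word statistics) plus a controlled
  stationary GC content, the two signals a composition-based binner can
  exploit.  Genomes simulated from the models supply pre-training windows
  for the feature-extraction CNN and held-out contigs for benchmarking.

* **GC groups** — two groups of i.i.d.-base random sequences at x% and
  (100 - x)% GC, the controlled experiment that probes whether a feature
  separates sequences purely by GC content.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import ALPHABET, DnaSequence

_GC_ROWS = np.array([0.0, 1.0, 1.0, 0.0])  # indicator of G/C among (A,C,G,T)


@dataclass
class SpeciesModel:
    """Order-``order`` Markov chain over (A, C, G, T).

    ``transitions`` has shape (4**order, 4); row ``c`` is the distribution of
    the next base given the context with base-4 code ``c`` (A=0 .. T=3).
    """

    species_id: str
    order: int
    transitions: np.ndarray
    gc_target: float

    def __post_init__(self) -> None:
        t = np.asarray(self.transitions, dtype=float)
        if t.shape != (4**self.order, 4):
            raise ValueError(f"transitions must have shape ({4 ** self.order}, 4)")
        if (t < 0).any():
            raise ValueError("transition probabilities must be nonnegative")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each conditional distribution must sum to 1")
        self.transitions = t

    def stationary_context_distribution(self) -> np.ndarray:
        """Stationary distribution over the 4**order contexts (power iteration)."""
        n_ctx = 4**self.order
        # context c = (b_1..b_r) moves to (b_2..b_r, b) with prob P(b | c)
        nxt = (np.arange(n_ctx)[:, None] * 4) % n_ctx + np.arange(4)[None, :]
        pi = np.full(n_ctx, 1.0 / n_ctx)
        for _ in range(2000):
            new = np.zeros(n_ctx)
            np.add.at(new, nxt, pi[:, None] * self.transitions)
            if np.abs(new - pi).sum() < 1e-13:
                pi = new
                break
            pi = new
        return pi

    def stationary_gc(self) -> float:
        """GC fraction of the chain's stationary base distribution."""
        pi = self.stationary_context_distribution()
        base_marginal = pi.reshape(-1, 4).sum(axis=0)  # last base of the context
        return float(base_marginal @ _GC_ROWS)


@dataclass
class GcGroupSpec:
    """Two groups of random i.i.d.-base sequences at x% and (100 - x)% GC."""

    x: float
    n_per_group: int = 500
    seq_length: int = 5120
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.x < 100:
            raise ValueError("x must be strictly between 0 and 100")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")


@dataclass
class LabeledDataset:
    """Sequences with aligned ground-truth class labels."""

    sequences: list[DnaSequence]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.labels):
            raise ValueError("sequences and labels must have equal length")
        if any(not lab for lab in self.labels):
            raise ValueError("labels must be nonempty strings")

    def __len__(self) -> int:
        return len(self.sequences)


def _gc_base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _tilt_to_gc(transitions: np.ndarray, order: int, gc_target: float) -> np.ndarray:
    """Exponentially tilt G/C columns so the stationary GC hits ``gc_target``.

    Rows are reweighted as P'(b|c) ∝ P(b|c) * w**1[b in {G,C}]; the scalar
    w is found by bisection on log w, which is monotone in stationary GC.
    """

    def tilted(log_w: float) -> np.ndarray:
        w = np.exp(log_w * _GC_ROWS)
        t = transitions * w[None, :]
        return t / t.sum(axis=1, keepdims=True)

    def gc_of(log_w: float) -> float:
        m = SpeciesModel("tmp", order, tilted(log_w), gc_target)
        return m.stationary_gc()

    lo, hi = -12.0, 12.0
    for _ in range(80):
        mid = (lo + hi) / 2
        if gc_of(mid) < gc_target:
            lo = mid
        else:
            hi = mid
    return tilted((lo + hi) / 2)


def sample_species_model(
    seed: int,
    gc_target: float,
    divergence: float,
    order: int = 2,
    species_id: str | None = None,
) -> SpeciesModel:
    """Draw a random species model with the requested stationary GC content.

    Transition rows are Dirichlet(p / divergence) draws around the base
    distribution ``p`` implied by ``gc_target``; ``divergence`` -> 0 recovers
    ``p`` exactly in every row, larger values give stronger species-specific
    texture.  After the draw, rows are exponentially tilted so the stationary
    GC matches ``gc_target`` to ~1e-4 (well inside the 0.02 contract).
    """
    if not 0 < gc_target < 1:
        raise ValueError("gc_target must be in (0, 1)")
    if divergence <= 0:
        raise ValueError("divergence must be > 0")
    if order < 0:
        raise ValueError("order must be >= 0")
    rng = np.random.default_rng(seed)
    base = _gc_base_probs(gc_target)
    alpha = base / divergence
    rows = rng.dirichlet(alpha, size=4**order)
    rows = np.maximum(rows, 1e-12)
    rows /= rows.sum(axis=1, keepdims=True)
    rows = _tilt_to_gc(rows, order, gc_target)
    return SpeciesModel(
        species_id=species_id or f"species_{seed}",
        order=order,
        transitions=rows,
        gc_target=gc_target,
    )


def simulate_genome(model: SpeciesModel, length: int, seed: int) -> DnaSequence:
    """Simulate one genome of ``length`` bp from the Markov chain."""
    if length < model.order + 1:
        raise ValueError("length must be at least order + 1")
    rng = np.random.default_rng(seed)
    n_ctx = 4**model.order
    cum = np.cumsum(model.transitions, axis=1)
    cum[:, -1] = 1.0  # guard against rounding
    u = rng.random(length)
    bases = np.empty(length, dtype=np.int8)
    # seed the first `order` bases from the stationary context distribution
    if model.order > 0:
        ctx_dist = model.stationary_context_distribution()
        ctx = int(rng.choice(n_ctx, p=ctx_dist / ctx_dist.sum()))
        c = ctx
        for i in range(model.order - 1, -1, -1):  # decode context, most significant first
            bases[i] = c % 4
            c //= 4
        start = model.order
    else:
        ctx = 0
        start = 0
    for i in range(start, length):
        b = int(np.searchsorted(cum[ctx], u[i], side="right"))
        bases[i] = b
        ctx = (ctx * 4 + b) % n_ctx
    residues = "".join(ALPHABET[b] for b in bases)
    return DnaSequence(id=f"{model.species_id}_genome", residues=residues)


def make_pretraining_set(
    models: list[SpeciesModel],
    windows_per_species: int,
    seed: int,
    genome_length: int = 100_000,
    window_length: int = 1024,
) -> LabeledDataset:
    """Simulate one genome per species and extract random fixed-length windows.

    Windows are uniform random substrings (with replacement) of the simulated
    genome, labeled with the species id — the training material for the
    species-classification pre-training task.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 species models")
    if windows_per_species < 1:
        raise ValueError("windows_per_species must be >= 1")
    if genome_length < window_length:
        raise ValueError(
            f"genome_length {genome_length} is shorter than the window length {window_length}"
        )
    root = np.random.default_rng(seed)
    sequences: list[DnaSequence] = []
    labels: list[str] = []
    for model in models:
        genome_seed = int(root.integers(2**31))
        genome = simulate_genome(model, genome_length, genome_seed)
        starts = root.integers(0, genome.length - window_length + 1, size=windows_per_species)
        for j, s in enumerate(starts):
            sequences.append(
                DnaSequence(
                    id=f"{model.species_id}_w{j}",
                    residues=genome.residues[s : s + window_length],
                )
            )
            labels.append(model.species_id)
    return LabeledDataset(sequences, labels)


def make_benchmark_contigs(
    models: list[SpeciesModel],
    contigs_per_species: int,
    contig_length: int,
    seed: int,
) -> LabeledDataset:
    """Held-out contigs for binning benchmarks: fresh genomes, fixed-length cuts."""
    if len(models) < 2:
        raise ValueError("need at least 2 species models")
    root = np.random.default_rng(seed)
    sequences: list[DnaSequence] = []
    labels: list[str] = []
    for model in models:
        genome_len = max(contigs_per_species * contig_length, contig_length) + model.order + 1
        genome = simulate_genome(model, genome_len, int(root.integers(2**31)))
        for j in range(contigs_per_species):
            s = j * contig_length
            sequences.append(
                DnaSequence(
                    id=f"{model.species_id}_contig{j}",
                    residues=genome.residues[s : s + contig_length],
                )
            )
            labels.append(model.species_id)
    return LabeledDataset(sequences, labels)


def make_gc_groups(spec: GcGroupSpec) -> LabeledDataset:
    """Generate the two random GC-content groups.

    Group 1 draws bases i.i.d. with P(G) = P(C) = x/200 and
    P(A) = P(T) = (100 - x)/200; group 2 swaps x for 100 - x.
    """
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(ALPHABET))
    sequences: list[DnaSequence] = []
    labels: list[str] = []
    for group, gc_pct in (("group1", spec.x), ("group2", 100.0 - spec.x)):
        probs = _gc_base_probs(gc_pct / 100.0)
        draws = rng.choice(4, size=(spec.n_per_group, spec.seq_length), p=probs)
        for i in range(spec.n_per_group):
            sequences.append(
                DnaSequence(
                    id=f"{group}_seq{i}",
                    residues="".join(letters[draws[i]]),
                )
            )
            labels.append(group)
    return LabeledDataset(sequences, labels)


def simulate_coverage(
    labels: list[str],
    abundance: dict[str, float],
    noise_sd: float,
    seed: int,
) -> np.ndarray:
    """Per-sequence coverage: class abundance plus Gaussian noise, clipped at 0."""
    missing = sorted(set(labels) - set(abundance))
    if missing:
        raise ValueError(f"no abundance given for labels: {missing}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    means = np.array([abundance[lab] for lab in labels], dtype=float)
    cov = means + rng.normal(0.0, noise_sd, size=len(labels)) if noise_sd > 0 else means.copy()
    return np.maximum(cov, 0.0)


def write_truth_table(path, dataset: LabeledDataset) -> None:
    """Tab-separated (sequence_id, label) ground-truth table."""
    with open(path, "w") as fh:
        fh.write("sequence_id\tlabel\n")
        for seq, lab in zip(dataset.sequences, dataset.labels):
            fh.write(f"{seq.id}\t{lab}\n")


def write_coverage_table(path, ids: list[str], coverage: np.ndarray) -> None:
    """Tab-separated (sequence_id, coverage) table."""
    with open(path, "w") as fh:
        fh.write("sequence_id\tcoverage\n")
        for sid, cov in zip(ids, coverage):
            fh.write(f"{sid}\t{cov:.6g}\n")
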