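"""Bitstring genomes and the feed-forward neural controller they encode.

Each agent carries a genome of 33 genes, one 8-bit unsigned integer per
gene (264 bits total).  Genes map linearly onto the 33 connection weights
of a feed-forward network with 6 sensory inputs plus a constant bias input
of -1, 3 hidden neurons and 3 output neurons (left wheel, right wheel,
share signal), all with tanh activation.  The layer sizes give
7*3 + 4*3 = 33 weights: the bias input feeds both the hidden and the
output layer, which is the only wiring consistent with a 33-gene genome.

Gene-to-weight order (fixed, relied upon by serialization):
genes 0..20 fill the input->hidden matrix row-major (input index major,
hidden index minor; input 6 is the bias), genes 21..32 fill the
hidden+bias->output matrix row-major (source 3 is the bias).

Bit order within a gene is most-significant-bit first, so "the third bit"
of a gene carries weight 2**5 = 32.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_GENES = 33
BITS_PER_GENE = 8
N_BITS = N_GENES * BITS_PER_GENE  # 264

N_SENSORS = 6
N_INPUTS = N_SENSORS + 1  # + bias
N_HIDDEN = 3
N_OUTPUTS = 3
N_WEIGHTS = N_INPUTS * N_HIDDEN + (N_HIDDEN + 1) * N_OUTPUTS  # 33

BIAS_VALUE = -1.0

#: bit value of "the third of the eight bits" (MSB-first convention)
THIRD_BIT_VALUE = 32

DEFAULT_WEIGHT_RANGE = 1.0


def _as_gene_array(genes) -> np.ndarray:
    arr = np.asarray(genes)
    if arr.shape != (N_GENES,):
        raise ValueError(f"genome must have exactly {N_GENES} genes, got shape {arr.shape}")
    if arr.dtype.kind not in "iu" and not np.all(arr == np.floor(arr)):
        raise ValueError("gene values must be integers")
    arr = arr.astype(np.int64)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("gene values must lie in [0, 255]")
    return arr.astype(np.uint8)


@dataclass(frozen=True)
class Genome:
    """An agent genome: 33 genes, each an integer in [0, 255]."""

    genes: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "genes", _as_gene_array(self.genes))
        self.genes.flags.writeable = False

    # -- bitstring view ------------------------------------------------
    def to_bits(self) -> np.ndarray:
        """264-element 0/1 array, MSB-first within each gene."""
        return np.unpackbits(self.genes)

    @classmethod
    def from_bits(cls, bits) -> "Genome":
        bits = np.asarray(bits, dtype=np.uint8)
        if bits.shape != (N_BITS,):
            raise ValueError(f"expected {N_BITS} bits, got shape {bits.shape}")
        return cls(np.packbits(bits))

    # -- text forms (see io module for file-level round-trips) ---------
    def to_hex(self) -> str:
        return self.genes.tobytes().hex()

    @classmethod
    def from_hex(cls, s: str) -> "Genome":
        if len(s) != 2 * N_GENES:
            raise ValueError(f"hex genome must have {2 * N_GENES} characters, got {len(s)}")
        return cls(np.frombuffer(bytes.fromhex(s), dtype=np.uint8))

    def to_text(self) -> str:
        """One-line record: 33 space-separated integers."""
        return " ".join(str(int(v)) for v in self.genes)

    @classmethod
    def from_text(cls, line: str) -> "Genome":
        tokens = line.split()
        if len(tokens) == 1:
            return cls.from_hex(tokens[0])
        return cls([int(t) for t in tokens])

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and bool(np.array_equal(self.genes, other.genes))

    def __hash__(self) -> int:
        return hash(self.genes.tobytes())


def random_genome(rng: np.random.Generator) -> Genome:
    return Genome(rng.integers(0, 256, size=N_GENES, dtype=np.uint8))


def random_population(n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 33) uint8 array of uniform-random genomes."""
    return rng.integers(0, 256, size=(n, N_GENES), dtype=np.uint8)


@dataclass(frozen=True)
class ControllerNetwork:
    """Decoded controller: weights of the 7->3->3 tanh network.

    ``w_in`` is (7, 3): rows are the 6 sensors plus the bias input,
    columns the hidden neurons.  ``w_out`` is (4, 3): rows are the 3
    hidden neurons plus the bias input, columns the outputs
    (left wheel, right wheel, share signal).
    """

    w_in: np.ndarray
    w_out: np.ndarray
    weight_range: float = DEFAULT_WEIGHT_RANGE

    def __post_init__(self):
        w_in = np.asarray(self.w_in, dtype=float)
        w_out = np.asarray(self.w_out, dtype=float)
        if w_in.shape != (N_INPUTS, N_HIDDEN):
            raise ValueError(f"w_in must be {(N_INPUTS, N_HIDDEN)}, got {w_in.shape}")
        if w_out.shape != (N_HIDDEN + 1, N_OUTPUTS):
            raise ValueError(f"w_out must be {(N_HIDDEN + 1, N_OUTPUTS)}, got {w_out.shape}")
        if self.weight_range <= 0:
            raise ValueError("weight_range must be positive")
        W = self.weight_range
        if np.abs(w_in).max() > W + 1e-12 or np.abs(w_out).max() > W + 1e-12:
            raise ValueError(f"weights must lie in [-{W}, {W}]")
        object.__setattr__(self, "w_in", w_in)
        object.__setattr__(self, "w_out", w_out)

    @property
    def n_weights(self) -> int:
        return self.w_in.size + self.w_out.size


@dataclass(frozen=True)
class MotorCommand:
    left_speed: float
    right_speed: float
    share_signal: float


def genes_to_weights(genes: np.ndarray, weight_range: float = DEFAULT_WEIGHT_RANGE) -> np.ndarray:
    """Linear gene->weight map w = W * (2 g / 255 - 1), elementwise.

    Works on arrays of any shape whose last axis has 33 genes; used both
    for single genomes and for whole populations at once.
    """
    g = np.asarray(genes, dtype=float)
    return weight_range * (2.0 * g / 255.0 - 1.0)


def decode_genome(genome: Genome, weight_range: float = DEFAULT_WEIGHT_RANGE) -> ControllerNetwork:
    """Decode a genome into its controller network.

    Gene 0 maps to weight -W, gene 255 to +W; the quantization step is
    2W/255, so no gene decodes to exactly zero.
    """
    w = genes_to_weights(genome.genes, weight_range)
    w_in = w[: N_INPUTS * N_HIDDEN].reshape(N_INPUTS, N_HIDDEN)
    w_out = w[N_INPUTS * N_HIDDEN :].reshape(N_HIDDEN + 1, N_OUTPUTS)
    return ControllerNetwork(w_in=w_in, w_out=w_out, weight_range=weight_range)


def activate(net: ControllerNetwork, sensors) -> MotorCommand:
    """One forward pass: hidden_j = tanh(sum_i w_ij x_i) with bias -1."""
    s = np.asarray(sensors, dtype=float)
    if s.shape != (N_SENSORS,):
        raise ValueError(f"sensor vector must have {N_SENSORS} entries, got {s.shape}")
    x = np.append(s, BIAS_VALUE)
    h = np.tanh(x @ net.w_in)
    out = np.tanh(np.append(h, BIAS_VALUE) @ net.w_out)
    return MotorCommand(left_speed=out[0], right_speed=out[1], share_signal=out[2])


# ---------------------------------------------------------------------
# Variation operators
# ---------------------------------------------------------------------

def mutate_genes(genes: np.ndarray, per_bit_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-bit mutation on a (..., 33) uint8 gene array; returns a new array."""
    if not 0.0 <= per_bit_rate <= 1.0:
        raise ValueError("per-bit mutation rate must be in [0, 1]")
    genes = np.asarray(genes, dtype=np.uint8)
    flips = rng.random(genes.shape + (BITS_PER_GENE,)) < per_bit_rate
    # MSB-first bit weights 128..1
    weights = (1 << np.arange(BITS_PER_GENE - 1, -1, -1)).astype(np.uint8)
    mask = (flips * weights).sum(axis=-1).astype(np.uint8)
    return genes ^ mask


def mutate(genome: Genome, per_bit_rate: float, rng: np.random.Generator) -> Genome:
    """Flip each of the 264 bits independently with probability ``per_bit_rate``."""
    return Genome(mutate_genes(genome.genes, per_bit_rate, rng))


def crossover(parent_a: Genome, parent_b: Genome, prob: float,
              rng: np.random.Generator) -> tuple[Genome, Genome]:
    """Single-point crossover at a uniformly chosen internal bit boundary.

    With probability ``prob`` the two 264-bit strings are cut at the same
    boundary k in 1..263 and the tails swapped; otherwise the parents are
    returned unchanged (as copies).
    """
    if not 0.0 <= prob <= 1.0:
        raise ValueError("crossover probability must be in [0, 1]")
    if rng.random() >= prob:
        return Genome(parent_a.genes.copy()), Genome(parent_b.genes.copy())
    k = int(rng.integers(1, N_BITS))
    ba, bb = parent_a.to_bits(), parent_b.to_bits()
    child_a = np.concatenate([ba[:k], bb[k:]])
    child_b = np.concatenate([bb[:k], ba[k:]])
    return Genome.from_bits(child_a), Genome.from_bits(child_b)


def crossover_at(parent_a: Genome, parent_b: Genome, k: int) -> tuple[Genome, Genome]:
    """Deterministic single-point crossover at bit boundary k (1..263)."""
    if not 1 <= k <= N_BITS - 1:
        raise ValueError("cut point must be an internal bit boundary")
    ba, bb = parent_a.to_bits(), parent_b.to_bits()
    return (Genome.from_bits(np.concatenate([ba[:k], bb[k:]])),
            Genome.from_bits(np.concatenate([bb[:k], ba[k:]])))


def flip_third_bit(genome: Genome, gene_index: int) -> Genome:
    """Flip the third-most-significant bit of one gene (mutation size +/-32).

    This is the medium-effect point mutation used by the mutation-effect
    screens: the decoded weight always moves by exactly 32 gene units.
    """
    if not 0 <= gene_index < N_GENES:
        raise ValueError(f"gene_index must be in [0, {N_GENES - 1}]")
    genes = genome.genes.copy()
    genes[gene_index] ^= THIRD_BIT_VALUE
    return Genome(genes)
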