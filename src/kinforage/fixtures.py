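"""Deterministic test fixtures: random populations and scripted controllers.

The scripted controllers are realized as hand-built genomes (so they
pass through the same decode/simulate path as evolved individuals):

* ``wall-seeker`` — drives forward and steers toward the white wall
  using the two vision channels: hidden neuron 1 computes the
  left-minus-right vision difference, hidden neuron 2 a constant
  forward drive, and the wheel weights turn the robot toward whichever
  half-field sees the wall.  Hidden neuron 0 feeds only the share
  output and sets the share sign.
* ``always-share`` / ``never-share`` — the same chassis with the
  bias-to-share weight saturated so the share output is strictly
  positive (resp. negative) for every possible sensor input.

The base wall-seeker's share circuit is deliberately balanced near its
threshold: flipping the third bit of gene 18 (the bias-to-hidden-0
weight, 16 -> 48) moves the share output from always-positive to
always-negative while leaving the wheels essentially untouched — a
constructed pure-altruism mutation used to validate the pleiotropy
screen's classification.
"""

from __future__ import annotations

import numpy as np

from .genome import N_GENES, Genome, random_population

#: gene index of the bias->hidden-0 weight; third-bit flip turns the
#: base wall-seeker from always-share into never-share
SHARE_SWITCH_GENE = 18

FIXTURE_KINDS = ("random", "always-share", "never-share", "wall-seeker")


def wall_seeker_genes() -> np.ndarray:
    """33-gene array of the hand-built wall-seeking controller."""
    g = np.full(N_GENES, 127, dtype=np.uint8)  # gene 127 ~ weight -0.004
    # steering: h1 = tanh(vision_left - vision_right)
    g[13] = 255   # vision-left  -> h1, weight +1
    g[16] = 0     # vision-right -> h1, weight -1
    # share circuit: h0 = tanh(0.8745 + noise), compared against 0.6314
    g[18] = 16    # bias -> h0, weight -0.8745
    g[23] = 255   # h0 -> share, weight +1
    g[32] = 208   # bias -> share, weight 0.6314 (subtracted via bias = -1)
    # forward drive: h2 = tanh(+1 + noise) ~ 0.76
    g[20] = 0     # bias -> h2, weight -1
    g[24] = 0     # h1 -> left wheel, weight -1 (turn toward the wall)
    g[25] = 255   # h1 -> right wheel, weight +1
    g[27] = 255   # h2 -> left wheel, weight +1
    g[28] = 255   # h2 -> right wheel, weight +1
    return g


def make_fixtures(kind: str, seed: int = 0, n_robots: int = 8) -> np.ndarray:
    """Deterministic fixture group: (n_robots, 33) uint8 gene array."""
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; known: {FIXTURE_KINDS}")
    if kind == "random":
        return random_population(n_robots, np.random.default_rng(seed))
    g = wall_seeker_genes()
    if kind == "always-share":
        g[32] = 0     # bias -> share weight -1: share = tanh(h0 + 1) > 0
    elif kind == "never-share":
        g[32] = 255   # bias -> share weight +1: share = tanh(h0 - 1) < 0
    return np.tile(g, (n_robots, 1))


def wall_seeker_genome(share: str | None = None) -> Genome:
    """Single wall-seeker Genome; ``share`` in {None, 'always', 'never'}."""
    g = wall_seeker_genes()
    if share == "always":
        g[32] = 0
    elif share == "never":
        g[32] = 255
    elif share is not None:
        raise ValueError("share must be None, 'always' or 'never'")
    return Genome(g)
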