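"""Upstream RNA structure and its association with 3' end abundance.

A 3'→5' exoribonuclease stalling at a stem-loop leaves a 3' end just
downstream of the structure, so the predicted minimum free energy (MFE,
kcal/mol) of the 40 nt immediately upstream of a 3' end is the natural
covariate for its abundance: the more negative the ΔG, the stronger the
obstacle. The window excludes the 3'-end base itself.

Two folding engines are available. ``builtin`` is a deliberately reduced
nearest-neighbor dynamic program — canonical and wobble pairs, published
stacking energies, a flat hairpin-closing penalty, minimum loop of 3, no
bulge/internal-loop asymmetry tables — adequate because every statistic in
this module depends only on ΔG ordering and sign. ``external`` shells out to
a user-configured folding tool (e.g. ``RNAfold``) and parses its MFE.
"""

from __future__ import annotations

import re
import shutil
import subprocess
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .compare import distribution_test

DEFAULT_DG_WINDOW = 40

_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_PAIRS = {"AU", "UA", "CG", "GC", "GU", "UG"}
_MIN_LOOP = 3  # unpaired bases enclosed by a hairpin pair

#: flat destabilizing penalty for closing a hairpin loop, kcal/mol
HAIRPIN_PENALTY = 4.0

#: stacking free energies, kcal/mol at 37 °C, indexed by (outer pair, inner
#: pair) where the outer pair is (5' base, 3' base); values are the standard
#: nearest-neighbor Watson-Crick/wobble stack subset
STACK_ENERGY = {
    ("AU", "AU"): -0.9, ("AU", "UA"): -1.1, ("AU", "CG"): -2.2,
    ("AU", "GC"): -2.1, ("AU", "GU"): -0.6, ("AU", "UG"): -1.4,
    ("UA", "AU"): -1.3, ("UA", "UA"): -0.9, ("UA", "CG"): -2.4,
    ("UA", "GC"): -2.1, ("UA", "GU"): -1.0, ("UA", "UG"): -1.3,
    ("CG", "AU"): -2.1, ("CG", "UA"): -2.1, ("CG", "CG"): -3.3,
    ("CG", "GC"): -2.4, ("CG", "GU"): -1.4, ("CG", "UG"): -2.1,
    ("GC", "AU"): -2.4, ("GC", "UA"): -2.2, ("GC", "CG"): -3.4,
    ("GC", "GC"): -3.3, ("GC", "GU"): -1.5, ("GC", "UG"): -2.5,
    ("GU", "AU"): -1.3, ("GU", "UA"): -1.4, ("GU", "CG"): -2.5,
    ("GU", "GC"): -2.1, ("GU", "GU"): -0.5, ("GU", "UG"): -0.4,
    ("UG", "AU"): -1.0, ("UG", "UA"): -0.6, ("UG", "CG"): -1.5,
    ("UG", "GC"): -1.4, ("UG", "GU"): -0.2, ("UG", "UG"): -0.5,
}


def upstream_sequence(coordinate: int, strand: str, genome_sequence: str,
                      window: int = DEFAULT_DG_WINDOW) -> tuple[str, bool]:
    """The ``window`` nt immediately 5' of (excluding) a 3'-end coordinate.

    Returns the transcript-sense RNA string (reverse-complemented on the −
    strand, T→U) and a flag marking truncation at the genome boundary.
    """
    n = len(genome_sequence)
    if not 1 <= coordinate <= n:
        raise ValueError(f"coordinate {coordinate} outside genome of length {n}")
    if strand == "+":
        lo = max(coordinate - window, 1)
        dna = genome_sequence[lo - 1 : coordinate - 1]
        truncated = lo > coordinate - window
        rna = dna.upper().replace("T", "U")
    else:
        hi = min(coordinate + window, n)
        dna = genome_sequence[coordinate : hi]
        truncated = hi < coordinate + window
        rna = dna.upper().replace("T", "U").translate(_COMPLEMENT)[::-1]
    return rna, truncated


# ---------------------------------------------------------------------------
# Folding engines
# ---------------------------------------------------------------------------

def _pair(seq: str, i: int, j: int) -> Optional[str]:
    p = seq[i] + seq[j]
    return p if p in _PAIRS else None


def _fold_builtin(seq: str) -> float:
    """Reduced nearest-neighbor MFE over nested structures.

    V[i][j]: best energy with (i, j) paired — closing a hairpin (flat
    penalty), stacking on (i+1, j-1), or enclosing any non-empty structure.
    W1[i][j]: best energy over structures of the subsequence with at least
    one pair; W1 may be positive (a lone pair costs the hairpin penalty),
    and such positive interiors can still beat the hairpin penalty inside an
    enclosing pair, so W1 is not clamped at zero. MFE = min(0, W1).
    """
    n = len(seq)
    INF = float("inf")
    V = np.full((n, n), INF)
    W1 = np.full((n, n), INF)
    for span in range(_MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            pij = _pair(seq, i, j)
            if pij is not None:
                best = HAIRPIN_PENALTY
                inner = _pair(seq, i + 1, j - 1)
                if inner is not None and V[i + 1][j - 1] < INF:
                    best = min(best, V[i + 1][j - 1] + STACK_ENERGY[(pij, inner)])
                if W1[i + 1][j - 1] < INF:
                    best = min(best, W1[i + 1][j - 1])
                V[i][j] = best
            # W1 recursion: j unpaired, or j paired with some k; a positive
            # left part is never beneficial, so the left uses min(0, W1)
            best_w = W1[i][j - 1]
            for k in range(i, j - _MIN_LOOP):
                if V[k][j] < INF:
                    left = min(0.0, W1[i][k - 1]) if k > i else 0.0
                    best_w = min(best_w, left + V[k][j])
            W1[i][j] = best_w
    if n == 0 or W1[0][n - 1] == INF:
        return 0.0
    return min(0.0, float(W1[0][n - 1]))


_MFE_RE = re.compile(r"\(\s*(-?\d+\.?\d*)\s*\)\s*$")


def _fold_external(seq: str, command: str) -> float:
    """Run an external folding tool and parse the trailing '( MFE )' field."""
    tool = command.split()[0]
    if shutil.which(tool) is None:
        raise FileNotFoundError(tool)
    proc = subprocess.run(command.split(), input=seq + "\n", text=True,
                          capture_output=True, check=True)
    for line in proc.stdout.splitlines():
        m = _MFE_RE.search(line.strip())
        if m:
            return float(m.group(1))
    raise ValueError(f"could not parse MFE from {tool} output")


def fold_mfe(seq: str, engine: str = "builtin",
             external_cmd: str = "RNAfold --noPS") -> float:
    """Minimum folding free energy of an RNA sequence, kcal/mol (<= 0)."""
    seq = seq.upper().replace("T", "U")
    if not seq:
        return 0.0
    if set(seq) - set("ACGU"):
        raise ValueError(f"invalid RNA characters in {seq!r}")
    if len(seq) < 4:
        return 0.0
    if engine == "builtin":
        return _fold_builtin(seq)
    if engine == "external":
        try:
            return min(0.0, _fold_external(seq, external_cmd))
        except (FileNotFoundError, subprocess.CalledProcessError) as exc:
            warnings.warn(f"external folding engine unavailable ({exc}); "
                          "falling back to builtin")
            return _fold_builtin(seq)
    raise ValueError(f"unknown engine {engine!r}")


# ---------------------------------------------------------------------------
# Association statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationResult:
    spearman_r: float
    spearman_p: float
    regression_slope: float
    regression_p: float
    n: int

    @property
    def degenerate(self) -> bool:
        return np.isnan(self.spearman_r)


def associate(norm_heights: Sequence[float], dgs: Sequence[float]
              ) -> AssociationResult:
    """Association of log10 normalized 3'-end abundance with upstream ΔG.

    Spearman rank correlation plus an OLS fit of log10(height) on ΔG with
    the slope t-test p. Callers pre-filter heights to qualifying 3' ends
    (normalized abundance >= 0.53). Zero variance in either variable yields
    NaN correlations, flagged via :attr:`AssociationResult.degenerate`.
    """
    h = np.asarray(norm_heights, dtype=float)
    g = np.asarray(dgs, dtype=float)
    if h.size != g.size:
        raise ValueError("paired inputs of unequal length")
    if h.size < 3:
        raise ValueError("need at least 3 pairs")
    y = np.log10(h)
    if np.allclose(h, h[0]) or np.allclose(g, g[0]):
        warnings.warn("zero variance; association undefined")
        return AssociationResult(float("nan"), float("nan"), float("nan"),
                                 float("nan"), int(h.size))
    rho, rho_p = stats.spearmanr(y, g)
    fit = stats.linregress(g, y)
    return AssociationResult(float(rho), float(rho_p), float(fit.slope),
                             float(fit.pvalue), int(h.size))


def subpopulation_dg_test(set_a_dgs: Sequence[float],
                          set_b_dgs: Sequence[float]) -> float:
    """One-tailed rank-sum p that set A's ΔGs are more negative (more stable
    structures) than set B's."""
    return distribution_test(set_a_dgs, set_b_dgs, alternative="less")
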