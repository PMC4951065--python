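"""Minimum-free-energy RNA folding by dynamic programming.

A deliberately simple base-pair energy model (Nussinov-style recursion with
per-pair stacking-free energies) so the package is self-contained and the
engine is exactly checkable against exhaustive structure enumeration:

* pair energies: GC = -3, AU = -2, GU = -1 (arbitrary kcal/mol-like units)
* hairpin loops must enclose at least ``MIN_LOOP`` (3) unpaired bases
* no pseudoknots (structures are non-crossing)

The optimal score is <= 0 because the empty structure has energy 0. A
thermodynamic folder (e.g. an external RNAfold wrapper) can be plugged in
at the :func:`dielomix.seqfeatures.compute_mfe` level.
"""

from __future__ import annotations

import numpy as np

MIN_LOOP = 3

_PAIR_ENERGY = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}

# 4x4 energy lookup, 0 for non-pairing combinations
_EMAT = np.zeros((4, 4))
for (_a, _b), _e in _PAIR_ENERGY.items():
    _EMAT[_BASE_INDEX[_a], _BASE_INDEX[_b]] = _e


def encode_rna(seq: str) -> np.ndarray:
    """Map an RNA/DNA string to integer codes, T->U; reject other characters."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"non-ACGTU characters in sequence: {sorted(bad)}")
    return np.fromiter((_BASE_INDEX[c] for c in s), dtype=np.int64, count=len(s))


def _mfe_dp_python(codes: np.ndarray, emat: np.ndarray, min_loop: int) -> float:
    n = len(codes)
    E = np.zeros((n + 1, n + 1))
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = E[i + 1, j]
            if E[i, j - 1] < best:
                best = E[i, j - 1]
            e = emat[codes[i], codes[j]]
            if e < 0.0:
                v = E[i + 1, j - 1] + e
                if v < best:
                    best = v
            for k in range(i + 1, j):
                v = E[i, k] + E[k + 1, j]
                if v < best:
                    best = v
            E[i, j] = best
    return float(E[0, n - 1]) if n > 0 else 0.0


try:  # pragma: no cover - exercised implicitly wherever numba is present
    from numba import njit

    _mfe_dp = njit(cache=False)(_mfe_dp_python)
    # trigger compilation on a tiny input at import time
    _mfe_dp(np.array([0, 0, 0, 0, 0], dtype=np.int64), _EMAT, MIN_LOOP)
except Exception:  # pragma: no cover
    _mfe_dp = _mfe_dp_python


def mfe_energy(seq: str) -> float:
    """Minimum folding energy of ``seq`` under the default pair-energy model."""
    codes = encode_rna(seq)
    if len(codes) <= MIN_LOOP + 1:
        return 0.0
    return _mfe_dp(codes, _EMAT, MIN_LOOP)
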