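"""Synthetic reference mutational signatures bundled with the package.

Twelve synthetic 96-channel signatures stand in for the breast-cancer
reference set (signatures 1, 2, 3, 5, 6, 8, 13, 17, 18, 20, 26, 30).  Each
is a Dirichlet draw whose concentration is boosted on a stylised set of
channels mimicking the broad character of its namesake (e.g. "Signature_1"
is dominated by C>T at NpCpG sites, the APOBEC pair 2/13 by TpC contexts,
the MMR-deficiency pair 20/26 by distinctive C>T and T>C profiles).  They
are *not* the empirically derived signatures; they exist so that refitting,
presence calling and association analyses can be exercised end to end
without external downloads.
"""

from __future__ import annotations

import functools
from importlib import resources

import numpy as np
import pandas as pd

from .contexts import CONTEXT_LABELS

_BUILD_SEED = 55117

SIGNATURE_NAMES: tuple[str, ...] = (
    "Signature_1", "Signature_2", "Signature_3", "Signature_5",
    "Signature_6", "Signature_8", "Signature_13", "Signature_17",
    "Signature_18", "Signature_20", "Signature_26", "Signature_30",
)


def _mask(predicate) -> np.ndarray:
    out = np.zeros(96)
    for i, lab in enumerate(CONTEXT_LABELS):
        five, ref, alt, three = lab[0], lab[2], lab[4], lab[6]
        if predicate(five, ref, alt, three):
            out[i] = 1.0
    return out


# stylised channel emphases, one per signature
_EMPHASES = {
    "Signature_1": lambda f, r, a, t: r == "C" and a == "T" and t == "G",
    "Signature_2": lambda f, r, a, t: f == "T" and r == "C" and a == "T",
    "Signature_3": lambda f, r, a, t: True,  # flat, HRD-like
    "Signature_5": lambda f, r, a, t: r == "T" and a == "C",
    "Signature_6": lambda f, r, a, t: f == "G" and r == "C" and a == "T",
    "Signature_8": lambda f, r, a, t: r == "C" and a == "A",
    "Signature_13": lambda f, r, a, t: f == "T" and r == "C" and a == "G",
    "Signature_17": lambda f, r, a, t: f == "C" and r == "T" and a == "G",
    "Signature_18": lambda f, r, a, t: r == "C" and a == "A" and t == "A",
    "Signature_20": lambda f, r, a, t: (f == "G" and r == "C" and a == "T" and t != "G")
    or (f == "A" and r == "T" and a == "C"),
    "Signature_26": lambda f, r, a, t: r == "T" and a == "C" and t == "G",
    "Signature_30": lambda f, r, a, t: r == "C" and a == "T" and f == "A",
}


def build_synthetic_signatures(seed: int = _BUILD_SEED) -> pd.DataFrame:
    """Deterministically construct the 96 x 12 synthetic reference matrix.

    Columns sum to one.  The bundled CSV is the frozen output of this
    function; a unit test keeps them in sync.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    for name in SIGNATURE_NAMES:
        mask = _mask(_EMPHASES[name])
        if name == "Signature_3":
            conc = np.full(96, 8.0)  # flat signature, mild wiggle
        else:
            conc = 0.05 + 8.0 * mask
        w = rng.dirichlet(conc)
        cols[name] = w
    mat = pd.DataFrame(cols, index=list(CONTEXT_LABELS))
    mat.index.name = "context"
    return mat


def signatures_to_csv(mat: pd.DataFrame) -> str:
    return mat.round(8).to_csv()


@functools.lru_cache(maxsize=1)
def load_reference_signatures():
    """Load the bundled synthetic signature matrix as a SignatureReference."""
    from .io import read_signature_reference

    path = resources.files("bcpgenomics.data").joinpath("signatures_breast_synthetic.csv")
    with resources.as_file(path) as p:
        return read_signature_reference(p)
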