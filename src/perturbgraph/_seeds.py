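"""Deterministic seed derivation.

Every randomized step in the package draws from a named child of a single
root seed, so a run is reproducible from one integer and each component's
stream is independent of the order in which components execute.
"""

from __future__ import annotations

import hashlib

import numpy as np

_MOD = 2**31 - 1


def derive_seed(root: int, *names: object) -> int:
    """Derive a child seed from ``root`` and a path of names.

    The same (root, names) pair always yields the same child; different
    names yield (cryptographically) unrelated children. Result is < 2**31.
    """
    h = hashlib.sha256()
    h.update(str(int(root)).encode())
    for name in names:
        h.update(b"/")
        h.update(str(name).encode())
    return int.from_bytes(h.digest()[:8], "big") % _MOD


def rng_for(root: int, *names: object) -> np.random.Generator:
    """A numpy Generator seeded by :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(root, *names))
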