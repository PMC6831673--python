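"""Deterministic seed derivation.

Every stochastic stage draws its seed from the master seed plus a named
context, so results do not depend on execution order and all randomness is a
pure function of (inputs, master seed).
"""

import hashlib


def derive_seed(master_seed: int, *context) -> int:
    """Derive a child seed from ``master_seed`` and a hashable context path.

    Counter-based: ``derive_seed(7, "module", 3)`` always yields the same
    value, independent of how many other seeds were drawn before it.  The
    result fits in a signed 32-bit integer (scikit-learn's accepted range).
    """
    key = repr((int(master_seed),) + tuple(context)).encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
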