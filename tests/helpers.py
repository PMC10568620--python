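"""Shared numeric helpers for the test suite."""

from __future__ import annotations


def rel(a: float, b: float) -> float:
    """Relative difference of ``a`` from reference ``b``."""
    return abs(a - b) / abs(b)


def max_rel_err(s1, s2) -> float:
    """Max per-genotype relative difference between two tumor states."""
    errs = []
    for name in "wxyz":
        a, b = getattr(s1, name), getattr(s2, name)
        denom = max(abs(a), abs(b))
        errs.append(abs(a - b) / denom if denom > 0 else 0.0)
    return max(errs)
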