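"""Anatomic stage grouping of breast tumours from TNM categories.

Maps clinical TNM triples (e.g. ``("T2", "N0", "M0")``) onto the aggregated
anatomic breast-cancer stages I-IV. The shipped lookup transcribes the AJCC
8th-edition anatomic stage groups; it can be replaced wholesale by passing a
custom ``groups`` mapping to :func:`map_tnm_to_stage`.

Conventions:

* Clinical/pathologic prefixes (``c``, ``p``, ``yc``, ``yp``, ``r``) and
  anatomic sub-letters (``T1c``, ``N1a`` ...) are stripped; ``T1mi`` and
  ``N1mi`` are kept distinct because micro-invasion/micro-metastasis changes
  the group.
* ``TX``/``NX``/``MX`` ("cannot be assessed") normalize to the missing
  sentinel (``None``).
* ``M1`` yields stage IV regardless of T and N; otherwise a missing
  indispensable component yields missing.
* In-situ-only disease (``Tis``) and ``T0 N0`` have no anatomic group within
  I-IV and map to missing.
"""

from __future__ import annotations

import re

__all__ = ["StagingError", "map_tnm_to_stage", "normalize_t", "normalize_n", "normalize_m"]


class StagingError(ValueError):
    """Raised for TNM category strings outside the controlled vocabulary."""


_PREFIX_RE = re.compile(r"^(?:y?[cpr])", re.IGNORECASE)

_T_RE = re.compile(r"^T(IS|X|0|1MI|[1-4])([A-D])?$", re.IGNORECASE)
_N_RE = re.compile(r"^N(X|0|1MI|[0-3])([A-C])?$", re.IGNORECASE)
_M_RE = re.compile(r"^M(X|0|1)$", re.IGNORECASE)

# (T, N) -> stage under M0; N1mi is collapsed to N1 for T2+ before lookup.
_STAGE_GROUPS: dict[tuple[str, str], str] = {
    ("T1", "N0"): "I",
    ("T0", "N1mi"): "I",
    ("T1", "N1mi"): "I",
    ("T0", "N1"): "II",
    ("T1", "N1"): "II",
    ("T2", "N0"): "II",
    ("T2", "N1"): "II",
    ("T3", "N0"): "II",
    ("T0", "N2"): "III",
    ("T1", "N2"): "III",
    ("T2", "N2"): "III",
    ("T3", "N1"): "III",
    ("T3", "N2"): "III",
    ("T4", "N0"): "III",
    ("T4", "N1"): "III",
    ("T4", "N2"): "III",
    ("T0", "N3"): "III",
    ("T1", "N3"): "III",
    ("T2", "N3"): "III",
    ("T3", "N3"): "III",
    ("T4", "N3"): "III",
}


def _prepare(raw: str | None) -> str | None:
    if raw is None:
        return None
    s = str(raw).strip()
    if not s or s.lower() in {"na", "n/a", "nan", "none", "null", "unknown", "missing"}:
        return None
    return _PREFIX_RE.sub("", s)


def normalize_t(raw: str | None) -> str | None:
    """Normalize a T category to one of T0, Tis, T1mi, T1-T4, or None."""
    s = _prepare(raw)
    if s is None:
        return None
    m = _T_RE.match(s)
    if m is None:
        raise StagingError(f"unrecognized T category: {raw!r}")
    core = m.group(1).upper()
    if core == "X":
        return None
    if core == "IS":
        return "Tis"
    if core == "1MI":
        return "T1mi"
    return f"T{core}"


def normalize_n(raw: str | None) -> str | None:
    """Normalize an N category to one of N0, N1mi, N1-N3, or None."""
    s = _prepare(raw)
    if s is None:
        return None
    m = _N_RE.match(s)
    if m is None:
        raise StagingError(f"unrecognized N category: {raw!r}")
    core = m.group(1).upper()
    if core == "X":
        return None
    if core == "1MI":
        return "N1mi"
    return f"N{core}"


def normalize_m(raw: str | None) -> str | None:
    """Normalize an M category to M0, M1, or None."""
    s = _prepare(raw)
    if s is None:
        return None
    m = _M_RE.match(s)
    if m is None:
        raise StagingError(f"unrecognized M category: {raw!r}")
    core = m.group(1).upper()
    if core == "X":
        return None
    return f"M{core}"


def map_tnm_to_stage(
    t: str | None,
    n: str | None,
    m: str | None,
    groups: dict[tuple[str, str], str] | None = None,
) -> str | None:
    """Map a TNM triple to an aggregated anatomic stage in {I, II, III, IV}.

    Returns ``None`` (missing) when an indispensable component is missing or
    the combination has no group within I-IV. Raises :class:`StagingError`
    for category strings outside the vocabulary.
    """
    groups = _STAGE_GROUPS if groups is None else groups
    t_n = normalize_t(t)
    n_n = normalize_n(n)
    m_n = normalize_m(m)

    if m_n == "M1":
        # distant metastasis determines stage IV on its own
        return "IV"
    if t_n is None or n_n is None or m_n is None:
        return None
    if t_n == "Tis":
        return None
    # T1mi groups with T1; N1mi only forms its own group for T0/T1
    if t_n == "T1mi":
        t_n = "T1"
    if n_n == "N1mi" and t_n not in ("T0", "T1"):
        n_n = "N1"
    return groups.get((t_n, n_n))
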