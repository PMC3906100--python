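"""Bundled emission-line and absorption-edge tables.

The tables are static CSV assets shipped with the package (generated once
from a standard fluorescence-line tabulation); nothing is queried at
runtime.  ``line_energy`` quotes the energy of the *strongest* member of a
Siegbahn group (Ka -> Ka1, Lb -> Lb1, ...), which is how group energies are
conventionally quoted in XRF work; the full multiplet with branching
fractions is available through ``line_group`` for building spectral models.
"""

from __future__ import annotations

import functools
from importlib import resources

import pandas as pd

from .core import EmissionLine

__all__ = ["line_energy", "line_group", "available_lines", "edge_energy",
           "fluorescence_yield", "line_table"]

_GROUPS = ("Ka", "Kb", "La", "Lb", "Lg", "Ma")
# Accept both Unicode-Greek and ASCII spellings of the group label.
_ALIASES = {
    "kα": "Ka", "kalpha": "Ka", "ka": "Ka",
    "kβ": "Kb", "kbeta": "Kb", "kb": "Kb",
    "lα": "La", "lalpha": "La", "la": "La",
    "lβ": "Lb", "lbeta": "Lb", "lb": "Lb",
    "lγ": "Lg", "lgamma": "Lg", "lg": "Lg",
    "mα": "Ma", "malpha": "Ma", "ma": "Ma",
}


def _normalize_label(label: str) -> str:
    key = label.strip().lower()
    if key in _ALIASES:
        return _ALIASES[key]
    raise KeyError(
        f"unknown line label {label!r}; expected one of {_GROUPS}"
    )


@functools.lru_cache(maxsize=1)
def line_table() -> pd.DataFrame:
    """The bundled emission-line table as a DataFrame."""
    with resources.files("paleoxrf.data").joinpath("xray_lines.csv").open() as f:
        return pd.read_csv(f, comment="#")


@functools.lru_cache(maxsize=1)
def _edge_table() -> pd.DataFrame:
    with resources.files("paleoxrf.data").joinpath("xray_edges.csv").open() as f:
        return pd.read_csv(f, comment="#")


def available_lines(element: str | None = None) -> list[tuple[str, str]]:
    """All (element, group) pairs in the table, optionally for one element."""
    df = line_table()
    if element is not None:
        df = df[df["element"] == element]
    return sorted({(e, g) for e, g in zip(df["element"], df["group"])})


def line_group(element: str, line_label: str) -> list[EmissionLine]:
    """All lines of an element's Siegbahn group with branching fractions."""
    group = _normalize_label(line_label)
    df = line_table()
    sel = df[(df["element"] == element) & (df["group"] == group)]
    if sel.empty:
        raise KeyError(
            f"no tabulated {group} lines for {element!r}; available: "
            f"{available_lines(element) or available_lines()}"
        )
    total = sel["rel_intensity"].sum()
    return [
        EmissionLine(element, group, float(r.energy_keV),
                     float(r.rel_intensity) / total)
        for r in sel.itertuples()
    ]


def line_energy(element: str, line_label: str) -> float:
    """Energy (keV) of the strongest line in the requested group."""
    lines = line_group(element, line_label)
    return max(lines, key=lambda l: l.relative_intensity).energy


def series_lines(element: str, series: str) -> list[EmissionLine]:
    """All lines of an element's K or L series, renormalized across groups.

    Groups are combined with fixed series branching (Ka:Kb = 0.88:0.12,
    La:Lb:Lg = 0.55:0.36:0.09), giving the unit-sum multiplet used as one
    column of the decomposition design matrix.
    """
    series = series.upper()
    if series == "K":
        weights = {"Ka": 0.88, "Kb": 0.12}
    elif series == "L":
        weights = {"La": 0.55, "Lb": 0.36, "Lg": 0.09}
    else:
        raise KeyError(f"unknown series {series!r}; expected 'K' or 'L'")
    out: list[EmissionLine] = []
    for group, w in weights.items():
        try:
            members = line_group(element, group)
        except KeyError:
            continue
        out.extend(
            EmissionLine(l.element, l.line_label, l.energy,
                         l.relative_intensity * w)
            for l in members
        )
    if not out:
        raise KeyError(f"no tabulated {series}-series lines for {element!r}")
    total = sum(l.relative_intensity for l in out)
    return [
        EmissionLine(l.element, l.line_label, l.energy,
                     l.relative_intensity / total)
        for l in out
    ]


def edge_energy(element: str, shell: str) -> float:
    """Absorption-edge energy (keV) of an element's K or L3 shell."""
    df = _edge_table()
    sel = df[(df["element"] == element) & (df["shell"] == shell.upper()[0])]
    if sel.empty:
        raise KeyError(f"no tabulated {shell} edge for {element!r}")
    return float(sel["edge_keV"].iloc[0])


def fluorescence_yield(element: str, shell: str) -> float:
    """Approximate fluorescence yield of the shell feeding the series."""
    df = _edge_table()
    sel = df[(df["element"] == element) & (df["shell"] == shell.upper()[0])]
    if sel.empty:
        raise KeyError(f"no tabulated yield for {element!r} {shell}")
    return float(sel["fluor_yield"].iloc[0])
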