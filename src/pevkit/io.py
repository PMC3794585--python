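"""TSV dialects for time courses, trajectories and clone panels.

All files are tab-separated with a required header row; lines starting
with ``#`` are metadata and are ignored on read. Fraction columns accept
``%``-suffixed values (divided by 100 on read), since plating tables mix
both conventions. Fractions are written with 6 decimals.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np

from .clones import ClonePanel
from .fitting import FRACTION_CEILING, TimeCourse
from .model import Trajectory

logger = logging.getLogger("pevkit")

__all__ = [
    "read_timecourse",
    "write_timecourse",
    "write_trajectory",
    "write_panel",
    "parse_fraction",
]

_TC_COLUMNS = ["generation", "selection_origin", "replicate", "frac_foa_r",
               "frac_ura", "n_nonselective", "n_ura", "n_foa"]
_TC_REQUIRED = ["generation", "selection_origin", "replicate", "frac_foa_r"]


def parse_fraction(token: str) -> float:
    """Parse a fraction, accepting a '%' suffix ("38%" -> 0.38)."""
    token = token.strip()
    if token.endswith("%"):
        return float(token[:-1]) / 100.0
    return float(token)


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def write_timecourse(courses, path, metadata: dict | None = None) -> None:
    """Write one or more time courses to the TSV dialect."""
    path = Path(path)
    lines = []
    for key, value in (metadata or {}).items():
        lines.append(f"# {key} = {value}")
    has_ura = any(c.frac_ura is not None for c in courses)
    has_counts = any(c.counts is not None for c in courses)
    cols = _TC_REQUIRED[:]
    if has_ura:
        cols.append("frac_ura")
    if has_counts:
        cols += ["n_nonselective", "n_ura", "n_foa"]
    lines.append("\t".join(cols))
    for c in courses:
        for i in range(len(c)):
            row = [f"{c.generations[i]:g}", c.selection_origin,
                   str(c.replicate), _fmt(c.frac_foa_r[i])]
            if has_ura:
                row.append(_fmt(c.frac_ura[i]) if c.frac_ura is not None else "")
            if has_counts:
                if c.counts is not None:
                    pc = c.counts[i]
                    row += [str(pc.n_nonselective), str(pc.n_ura), str(pc.n_foa)]
                else:
                    row += ["", "", ""]
            lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_timecourse(path) -> list[TimeCourse]:
    """Read the time-course TSV dialect, grouping rows by (origin, replicate).

    Malformed numeric fields raise with the offending line number;
    fractions outside [0, 1.2] raise naming the value. Input order is
    preserved within each group.
    """
    path = Path(path)
    header = None
    groups: dict[tuple[str, int], dict[str, list]] = {}
    order: list[tuple[str, int]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in _TC_REQUIRED if c not in header]
                if missing:
                    raise ValueError(
                        f"{path}: header missing required columns {missing}"
                    )
                continue
            row = dict(zip(header, fields))
            try:
                gen = float(row["generation"])
                rep = int(row["replicate"])
                foa = parse_fraction(row["frac_foa_r"])
                ura_tok = row.get("frac_ura", "").strip()
                ura = parse_fraction(ura_tok) if ura_tok else None
            except (KeyError, ValueError) as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed numeric field ({exc})"
                ) from None
            for name, v in (("frac_foa_r", foa), ("frac_ura", ura)):
                if v is not None and not (0.0 <= v <= FRACTION_CEILING):
                    raise ValueError(
                        f"{path}:{lineno}: {name} value {v} outside "
                        f"[0, {FRACTION_CEILING}]"
                    )
            origin = row["selection_origin"].strip()
            key = (origin, rep)
            if key not in groups:
                groups[key] = {"gen": [], "foa": [], "ura": []}
                order.append(key)
            groups[key]["gen"].append(gen)
            groups[key]["foa"].append(foa)
            groups[key]["ura"].append(ura)
    if header is None:
        raise ValueError(f"{path}: no header row found")
    if not groups:
        msg = f"{path}: no data rows (header and comments only)"
        warnings.warn(msg)
        logger.warning(msg)
        return []
    courses = []
    for origin, rep in order:
        g = groups[(origin, rep)]
        ura_vals = g["ura"]
        frac_ura = (np.array([u for u in ura_vals], dtype=float)
                    if all(u is not None for u in ura_vals) else None)
        courses.append(TimeCourse(
            selection_origin=origin,
            replicate=rep,
            generations=np.array(g["gen"]),
            frac_foa_r=np.array(g["foa"]),
            frac_ura=frac_ura,
        ))
    return courses


def write_trajectory(traj: Trajectory, path, metadata: dict | None = None) -> None:
    """Write a deterministic trajectory: generation, frac_active, frac_silent."""
    path = Path(path)
    meta = {"c_sa": traj.rates.c_sa, "c_as": traj.rates.c_as, "y0": traj.y0}
    meta.update(metadata or {})
    lines = [f"# {k} = {v}" for k, v in meta.items()]
    lines.append("generation\tfrac_active\tfrac_silent")
    for n, y in zip(traj.generations, traj.y_a):
        lines.append(f"{int(n)}\t{_fmt(y)}\t{_fmt(1.0 - y)}")
    path.write_text("\n".join(lines) + "\n")


def write_panel(panel: ClonePanel, path, metadata: dict | None = None,
                sorted_profile: bool = False) -> None:
    """Write a clone panel; optionally as the rank-ordered sorted profile."""
    path = Path(path)
    meta = {"c_sa": panel.rates.c_sa, "c_as": panel.rates.c_as,
            "n_gens": panel.n_gens,
            "founder_prob_active": panel.founder_prob_active,
            "seed": panel.seed}
    meta.update(metadata or {})
    lines = [f"# {k} = {v}" for k, v in meta.items()]
    if sorted_profile:
        lines.append("rank\tfrac_active")
        for rank, fa in enumerate(panel.sorted_profile()):
            lines.append(f"{rank}\t{_fmt(fa)}")
    else:
        lines.append("clone_index\tfounder_state\tfrac_active")
        for i, clone in enumerate(panel.clones):
            lines.append(f"{i}\t{clone.founder_state}\t{_fmt(clone.frac_active)}")
    path.write_text("\n".join(lines) + "\n")
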