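"""Recording, exporting and analyzing trajectories.

An :class:`Observation` captures, at one step: system-wide molecule totals,
the protocell census per classification class (``C`` empty, ``Cgr``,
``Cnrgr``, ... — the species combinations actually present), per-species
strand totals, and the mean membrane phospholipid ratio (RPM) per class.
:func:`detect_spread` turns a series into the categorical outcome used to
judge whether a species established itself: sustained presence in at least
``threshold`` protocells over a trailing window ("spread"), zero molecules
at the end ("extinct"), or neither ("undecided").
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from .world import POOL_SPECIES, World

__all__ = [
    "Observation",
    "observe",
    "detect_spread",
    "observations_frame",
    "snapshot",
    "export",
]

#: canonical species order for class labels (Cgr, Cnrgr, Cnrgrnpr, ...)
_LABEL_ORDER = ("NR", "GR", "NPR", "TR", "CTL")


def class_label(names) -> str:
    """Canonical label of a classification set: C, Cgr, Cnrgr, ..."""
    present = [n for n in _LABEL_ORDER if n in names]
    present += sorted(set(names) - set(_LABEL_ORDER))  # non-standard species
    return "C" + "".join(n.lower() for n in present)


@dataclass(frozen=True)
class Observation:
    """All recorded quantities of one sampled step."""

    step: int
    totals: dict            # system-wide Npp, Np, Nt, Gp, G
    free_fa: int
    free_pl: int
    membrane_fa: int
    membrane_pl: int
    n_protocells: int
    class_counts: dict      # label -> number of protocells
    species_cells: dict     # species -> protocells containing it
    species_strands: dict   # species -> strands containing its domain
    mean_rpm: dict = field(default_factory=dict)  # label -> mean RPM


def observe(w: World) -> Observation:
    """Record the current state of ``w`` (cheap, array-level)."""
    pool = w.pool
    totals = {
        "Npp": int(pool[:, K.NPP].sum()),
        "Np": int(pool[:, K.NP_].sum()),
        "Nt": int(pool[:, K.NTA:K.NTU + 1].sum()),
        "Gp": int(pool[:, K.GP].sum()),
        "G": int(pool[:, K.G].sum()),
    }
    st = w.strands
    top = int(st.meta[1])
    live = np.flatnonzero(st.alive[:top])
    flags = st.flags[:top][live]
    species_strands = {
        sp.name: int((flags & (1 << k) != 0).sum())
        for k, sp in enumerate(w.species)
    }
    rflags = np.zeros(w.R, np.uint8)
    np.bitwise_or.at(rflags, st.room[:top][live], flags)
    cells = np.flatnonzero(w.occ)
    cell_flags = rflags[cells]
    species_cells = {
        sp.name: int((cell_flags & (1 << k) != 0).sum())
        for k, sp in enumerate(w.species)
    }
    class_counts: dict[str, int] = {}
    mean_rpm: dict[str, float] = {}
    if cells.size:
        b = w.mem_fa[cells] + 2 * w.mem_pl[cells]
        with np.errstate(invalid="ignore"):
            rpm_vals = np.where(b > 0, 2.0 * w.mem_pl[cells] / b, 0.0)
        for mask in np.unique(cell_flags):
            names = {sp.name for k, sp in enumerate(w.species) if mask & (1 << k)}
            label = class_label(names)
            sel = cell_flags == mask
            class_counts[label] = int(sel.sum())
            mean_rpm[label] = float(rpm_vals[sel].mean())
    return Observation(
        step=w.step_count,
        totals=totals,
        free_fa=int(pool[:, K.FA].sum()),
        free_pl=int(pool[:, K.PL].sum()),
        membrane_fa=int(w.mem_fa.sum()),
        membrane_pl=int(w.mem_pl.sum()),
        n_protocells=int(cells.size),
        class_counts=class_counts,
        species_cells=species_cells,
        species_strands=species_strands,
        mean_rpm=mean_rpm,
    )


def detect_spread(observations, species: str, window: int = None,
                  threshold: int = 10) -> str:
    """Categorical outcome for one species over an observation series.

    "spread" if the species' protocell count stays >= ``threshold``
    throughout the trailing ``window`` observations (default: the final 10%
    of the series); "extinct" if its molecule total is zero at the end;
    otherwise "undecided".
    """
    if not observations:
        raise ValueError("empty observation series")
    if window is None:
        window = max(1, len(observations) // 10)
    if window > len(observations):
        raise ValueError("window longer than the series")
    tail = observations[-window:]
    if all(o.species_cells.get(species, 0) >= threshold for o in tail):
        return "spread"
    if observations[-1].species_strands.get(species, 0) == 0:
        return "extinct"
    return "undecided"


def observations_frame(observations) -> pd.DataFrame:
    """Flatten a series of observations into a tidy DataFrame.

    Columns: step, the molecule totals, membrane pools, n_protocells,
    ``cells_<SP>`` / ``mols_<SP>`` per species, ``count_<label>`` /
    ``rpm_<label>`` per observed classification class.
    """
    rows = []
    for o in observations:
        row = {"step": o.step, **o.totals,
               "free_FA": o.free_fa, "free_PL": o.free_pl,
               "membrane_FA": o.membrane_fa, "membrane_PL": o.membrane_pl,
               "n_protocells": o.n_protocells}
        row.update({f"cells_{k}": v for k, v in o.species_cells.items()})
        row.update({f"mols_{k}": v for k, v in o.species_strands.items()})
        row.update({f"count_{k}": v for k, v in o.class_counts.items()})
        row.update({f"rpm_{k}": v for k, v in o.mean_rpm.items()})
        rows.append(row)
    df = pd.DataFrame(rows)
    count_cols = [c for c in df.columns if c.startswith(("count_", "cells_", "mols_"))]
    df[count_cols] = df[count_cols].fillna(0).astype(int)
    rpm_cols = [c for c in df.columns if c.startswith("rpm_")]
    df[rpm_cols] = df[rpm_cols].fillna(0.0)  # absent class: RPM reported as 0
    return df


def snapshot(w: World) -> list[dict]:
    """Machine-readable spatial snapshot: one record per room.

    A structured spatial-distribution record:
    coordinates, molecule counts, membrane composition and RPM, and the set
    of species present in the room's strands.
    """
    rflags = w.room_flags()
    records = []
    for r in range(w.R):
        row, col = w.coords(r)
        rec = {
            "room": r, "row": row, "col": col,
            "counts": {name: int(w.pool[r, i]) for i, name in enumerate(POOL_SPECIES)},
            "protocell": bool(w.occ[r]),
            "species": sorted(sp.name for k, sp in enumerate(w.species)
                              if rflags[r] & (1 << k)),
        }
        if w.occ[r]:
            b = int(w.mem_fa[r] + 2 * w.mem_pl[r])
            rec["membrane"] = {"fa": int(w.mem_fa[r]), "pl": int(w.mem_pl[r])}
            rec["rpm"] = 2.0 * int(w.mem_pl[r]) / b if b else 0.0
        records.append(rec)
    return records


def export(result, out_dir, fasta: bool = False) -> dict[str, str]:
    """Write a run to ``out_dir``: time series CSV, snapshot and metadata
    JSON, optionally a FASTA dump of all strand sequences.

    Returns the paths written, keyed by artifact name.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    df = observations_frame(result.observations)
    paths["timeseries"] = os.path.join(out_dir, "timeseries.csv")
    df.to_csv(paths["timeseries"], index=False)
    w = result.world
    paths["snapshot"] = os.path.join(out_dir, "snapshot.json")
    with open(paths["snapshot"], "w") as fh:
        json.dump({"step": w.step_count, "N": w.N, "rooms": snapshot(w)}, fh)
    meta = {
        "seed": result.seed,
        "steps": w.step_count,
        "parameters": w.params.to_dict(),
        "species": [{"name": s.name, "domain": s.domain, "function": s.function}
                    for s in w.species],
        "material_log": [{"step": s, "pool": p, "amount": a}
                         for s, p, a in result.material_log],
    }
    paths["metadata"] = os.path.join(out_dir, "metadata.json")
    with open(paths["metadata"], "w") as fh:
        json.dump(meta, fh, indent=2)
    if fasta:
        st = w.strands
        top = int(st.meta[1])
        paths["strands"] = os.path.join(out_dir, "strands.fasta")
        with open(paths["strands"], "w") as fh:
            for s in np.flatnonzero(st.alive[:top]):
                r = int(st.room[s])
                loc = "inside" if w.occ[r] else "free"
                view = st.view(int(s), w.occ[r])
                fh.write(f">room{r}_slot{int(s)}|{loc}\n{view.sequence}\n")
    return paths
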