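"""Individual peak-vertex ROI selection and coordinate summaries.

For each child and hemisphere the ``k`` vertices (default 15) with the
highest window-averaged normalized 40 Hz ITPC are selected; the
hemisphere's ITPC, sustained-field amplitude and "MNI-like" coordinates
are then summarised as arithmetic means over that vertex set.  The
sustained field is extracted at the ITPC-selected vertices, never
peak-picked independently, so both measures describe the same cortical
patch.

In real data an anatomical ROI (the core auditory area) would restrict
the candidate vertices; here the per-hemisphere vertex cloud *is* the
ROI, and the hemisphere label is the subsetting field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ROISummary", "select_peak_vertices", "summarize_roi", "cohort_table"]

TABLE_COLUMNS = ["subject", "age", "hemisphere", "itpc", "erf", "x", "y", "z"]


@dataclass(frozen=True)
class ROISummary:
    """Per subject x hemisphere summary over the selected vertex set."""

    subject_id: str
    age_years: float
    hemisphere: str
    selected_vertices: tuple[int, ...]
    mean_norm_itpc: float  # percent-change units
    erf_amplitude: float  # z units
    mean_coords_mm: tuple[float, float, float]


def select_peak_vertices(
    itpc_window_avg: np.ndarray, hemisphere_labels: np.ndarray, k: int = 15
) -> dict[str, np.ndarray]:
    """The ``k`` highest-ITPC vertices per hemisphere.

    Ties are broken by ascending vertex id.  A hemisphere with fewer
    than ``k`` vertices contributes all of them (with a warning); an
    absent hemisphere raises.
    """
    import warnings

    values = np.asarray(itpc_window_avg, dtype=float)
    labels = np.asarray(hemisphere_labels)
    if len(values) != len(labels):
        raise ValueError("itpc vector and hemisphere labels disagree in length")
    out: dict[str, np.ndarray] = {}
    for hemi in ("left", "right"):
        vidx = np.flatnonzero(labels == hemi)
        if len(vidx) == 0:
            raise ValueError(f"no vertices labelled {hemi!r}")
        if len(vidx) < k:
            warnings.warn(
                f"hemisphere {hemi!r} has only {len(vidx)} vertices (< k={k}); taking all",
                stacklevel=2,
            )
            out[hemi] = np.sort(vidx)
            continue
        # stable sort on -value: equal values keep ascending-id order
        order = np.argsort(-values[vidx], kind="stable")[:k]
        out[hemi] = np.sort(vidx[order])
    return out


def summarize_roi(
    subject,
    vertex_sets: dict[str, np.ndarray],
    itpc_vals: np.ndarray,
    erf_vals: np.ndarray,
    coords_mm: np.ndarray | None = None,
) -> list[ROISummary]:
    """Mean ITPC, sustained amplitude and coordinates over each ROI."""
    coords = np.asarray(coords_mm if coords_mm is not None else subject.vertex_coords_mm)
    summaries = []
    for hemi, vidx in vertex_sets.items():
        summaries.append(
            ROISummary(
                subject_id=subject.subject_id,
                age_years=float(subject.age_years),
                hemisphere=hemi,
                selected_vertices=tuple(int(v) for v in vidx),
                mean_norm_itpc=float(np.mean(np.asarray(itpc_vals)[vidx])),
                erf_amplitude=float(np.mean(np.asarray(erf_vals)[vidx])),
                mean_coords_mm=tuple(coords[vidx].mean(axis=0)),
            )
        )
    return summaries


def cohort_table(summaries: list[ROISummary]) -> pd.DataFrame:
    """Long-format analysis table: one row per subject x hemisphere.

    Columns: subject, age, hemisphere, itpc, erf, x, y, z.  Feeding 30
    subjects with both hemispheres yields 60 rows.
    """
    if not summaries:
        raise ValueError("no ROI summaries to tabulate")
    rows = [
        {
            "subject": s.subject_id,
            "age": s.age_years,
            "hemisphere": s.hemisphere,
            "itpc": s.mean_norm_itpc,
            "erf": s.erf_amplitude,
            "x": s.mean_coords_mm[0],
            "y": s.mean_coords_mm[1],
            "z": s.mean_coords_mm[2],
        }
        for s in summaries
    ]
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    if table.duplicated(["subject", "hemisphere"]).any():
        dupes = table[table.duplicated(["subject", "hemisphere"], keep=False)]
        raise ValueError(
            f"duplicated subject/hemisphere rows: {sorted(set(dupes['subject']))}"
        )
    return table
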