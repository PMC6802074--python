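"""Bundled example data: wild-oat (Avena sterilis) seedling emergence.

Four replicate soil cylinders were inspected once or twice a week over a
winter-spring season; at each inspection the newly emerged seedlings were
counted and removed.  Cumulative hydrothermal time (CHTT) at each
inspection was computed for three candidate measuring depths (10, 20 and
50 mm), so the same counts come with three alternative grouping grids.
Totals per cylinder: 53, 61, 90 and 74 emerged seedlings (n = 278).
"""

from __future__ import annotations

import csv
import warnings
from importlib import resources

from .grouped_data import GroupedSample, InspectionRecord, from_inspection_records, pool

__all__ = ["load_wild_oat", "load_wild_oat_pooled", "DEPTHS", "CYLINDERS"]

DEPTHS = (10, 20, 50)
CYLINDERS = (1, 2, 3, 4)


def _rows():
    path = resources.files("groupedkde.data") / "avena_sterilis_emergence.csv"
    with path.open(newline="") as fh:
        yield from csv.DictReader(fh)


def load_wild_oat(depth: int = 10) -> list[GroupedSample]:
    """Per-cylinder grouped samples at a given depth (10, 20 or 50 mm)."""
    if depth not in DEPTHS:
        raise ValueError(f"depth must be one of {DEPTHS}")
    rows = list(_rows())
    samples = []
    for cyl in CYLINDERS:
        records = [
            InspectionRecord(float(r[f"chtt_{depth}mm"]), int(r[f"cylinder_{cyl}"]))
            for r in rows
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gs = from_inspection_records(records)
        samples.append(
            GroupedSample(gs.edges, gs.counts, gs.n_total, label=f"cylinder {cyl}, {depth} mm")
        )
    return samples


def load_wild_oat_pooled(depth: int = 10) -> GroupedSample:
    """The four cylinders pooled on the depth's CHTT grid (n = 278)."""
    return pool(load_wild_oat(depth), label=f"pooled, {depth} mm")
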