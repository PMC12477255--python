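"""Feature extraction: frequencies, pseudo-absolute counts, signaling.

Three feature families are computed per sample:

* **Frequencies** — each reported population as a percentage of the
  mononuclear (CD45+CD66−) denominator.  All frequency and pseudo-count
  comparisons use the unstimulated condition.
* **Pseudo-absolute counts** (blood only) — the CBC-derived mononuclear
  concentration, ``WBC − (neutrophils + eosinophils)`` cells/µL, multiplied
  by each population's frequency.
* **Signaling** — per-population median of arcsinh(x/5)-transformed
  signaling-marker intensity, and stimulation responses as the difference
  stimulated − unstimulated on that scale within the same animal, tissue
  and population.

Populations with fewer events than ``min_cells`` yield flagged-missing
medians; missingness propagates and is never imputed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .gating import GateResult, GateTree, PopulationCounts
from .synthetic import COFACTOR, EventMatrix, SampleMeta

FREQ_COLS = ["animal_id", "group", "tissue", "stim", "population", "frequency"]


def compute_frequencies(counts: list[tuple[SampleMeta, PopulationCounts]]
                        ) -> pd.DataFrame:
    """Population frequencies as percent of mononuclear events, per sample."""
    rows = []
    for meta, pc in counts:
        if pc.mononuclear_total <= 0:
            warnings.warn(
                f"{meta.sample_id}: zero mononuclear events; sample excluded")
            continue
        for pop, n in pc.counts.items():
            rows.append({
                "animal_id": meta.animal_id, "group": meta.group,
                "tissue": meta.tissue, "stim": meta.stim, "population": pop,
                "frequency": 100.0 * n / pc.mononuclear_total,
            })
    return pd.DataFrame(rows, columns=FREQ_COLS)


def pseudo_absolute_counts(freq_table: pd.DataFrame, cbc: pd.DataFrame
                           ) -> pd.DataFrame:
    """CBC-anchored counts, cells/µL of blood (PBMC, unstimulated only).

    mononuclear/µL = WBC − (neutrophils + eosinophils); each population's
    pseudo-absolute count is that concentration times its frequency.
    Animals without a CBC record get a flagged-missing row.
    """
    sub = freq_table[(freq_table["tissue"] == "PBMC")
                     & (freq_table["stim"] == "UNSTIM")]
    cbc = cbc.set_index("animal_id")
    mono = cbc["wbc"] - (cbc["neutrophils"] + cbc["eosinophils"])
    if (mono < 0).any():
        bad = mono[mono < 0].index.tolist()
        raise ValueError(f"negative mononuclear concentration for {bad}")
    rows = []
    for _, r in sub.iterrows():
        known = r["animal_id"] in mono.index
        value = mono[r["animal_id"]] * r["frequency"] / 100.0 if known \
            else np.nan
        rows.append({
            "animal_id": r["animal_id"], "group": r["group"],
            "population": r["population"], "cells_per_ul": value,
            "missing": not known,
        })
    return pd.DataFrame(
        rows, columns=["animal_id", "group", "population", "cells_per_ul",
                       "missing"])


def nested_corrected_frequencies(freq_table: pd.DataFrame, tree: GateTree
                                 ) -> pd.DataFrame:
    """Subtract reported-child frequencies from their reported parents.

    Makes overlapping parent/child gates (B ⊃ IgM+ B, CD8 T ⊃ activated
    CD8 T) disjoint for flow-style composition displays; values for nodes
    without reported children are unchanged.
    """
    out = freq_table.copy()
    keys = ["animal_id", "tissue", "stim"]
    reported = set(tree.reported)
    parent_children = {
        p: [c for c in tree.children(p) if c in reported]
        for p in reported}
    for p, kids in parent_children.items():
        if not kids:
            continue
        for _, grp in out.groupby(keys):
            pidx = grp.index[grp["population"] == p]
            if len(pidx) == 0:
                continue
            child_sum = grp.loc[grp["population"].isin(kids),
                                "frequency"].sum()
            corrected = out.loc[pidx[0], "frequency"] - child_sum
            if corrected < -1e-9:
                raise ValueError(
                    f"{p}: child frequencies exceed parent (containment "
                    "violated)")
            out.loc[pidx[0], "frequency"] = max(corrected, 0.0)
    return out


def arcsinh_median(events: EventMatrix, population_mask: np.ndarray,
                   marker: str, cofactor: float = COFACTOR,
                   min_cells: int = 20) -> float:
    """Median of arcsinh(x/cofactor) over a gated population.

    Returns NaN (flagged missing) when the population holds fewer than
    ``min_cells`` events.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    mask = np.asarray(population_mask, dtype=bool)
    if mask.sum() < min_cells:
        return float("nan")
    x = events.data.loc[mask, marker].to_numpy()
    return float(np.median(np.arcsinh(x / cofactor)))


SIG_COLS = ["animal_id", "group", "tissue", "stim", "population", "marker",
            "median"]


def signaling_medians(samples: list[tuple[SampleMeta, EventMatrix, GateResult]],
                      markers: list[str] | None = None,
                      cofactor: float = COFACTOR, min_cells: int = 20
                      ) -> pd.DataFrame:
    """Per-sample arcsinh medians for every (population, signaling marker)."""
    rows = []
    for meta, ev, gr in samples:
        markers_ = markers or ev.panel.signaling_channels
        for pop in gr.membership.columns:
            if pop == "mononuclear":
                continue
            mask = gr.membership[pop].to_numpy()
            for m in markers_:
                rows.append({
                    "animal_id": meta.animal_id, "group": meta.group,
                    "tissue": meta.tissue, "stim": meta.stim,
                    "population": pop, "marker": m,
                    "median": arcsinh_median(ev, mask, m, cofactor, min_cells),
                })
    return pd.DataFrame(rows, columns=SIG_COLS)


def stim_response(medians: pd.DataFrame, unstim: str = "UNSTIM"
                  ) -> pd.DataFrame:
    """Stimulated − unstimulated arcsinh medians per matched feature.

    Responses are computed within (animal, tissue, population, marker); a
    response is missing whenever either side is missing.
    """
    keys = ["animal_id", "group", "tissue", "population", "marker"]
    base = medians[medians["stim"] == unstim].set_index(keys)["median"]
    stim = medians[medians["stim"] != unstim]
    rows = []
    for _, r in stim.iterrows():
        key = tuple(r[k] for k in keys)
        u = base.get(key, np.nan)
        resp = r["median"] - u
        rows.append({**{k: r[k] for k in keys}, "stim": r["stim"],
                     "response": resp})
    out = pd.DataFrame(rows, columns=keys + ["stim", "response"])
    return out
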