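"""Fossil-based evaluation of hindcast niches.

Dated fossil occurrences are the only positive evidence of where species
lived in the past.  Each fossil's age window is resolved to the modeled
4-ky slice(s) whose paleoclimate is most compatible with its location
(highest combined MESS against the species' potential niche — the
conservative choice that minimizes ad hoc niche-change assumptions; exact
ties keep both slices).  The fossil's paleoclimate at the resolved slice
is then classified against the species' realized niche (convex hull of
modern occurrence climates) and potential niche (rectilinear envelope),
and summarized in per-species and per-variable deviation tables.
Physiological tolerance limits provide an independent congruence check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import interpolate_slice
from .grids import ClimateGrid, IsotopeSeries
from .mess import MessResult, mess_combined
from .niche import NicheEnvelope, cell_index, realized_membership

WITHIN_REALIZED = "within-realized"
WITHIN_POTENTIAL_ONLY = "within-potential-only"
OUTSIDE_POTENTIAL = "outside-potential"


class OutOfWindowError(ValueError):
    """Fossil age window does not intersect the modeled slices."""


class DataGapError(ValueError):
    """No paleoclimate available at the fossil's cell."""


@dataclass
class FossilRecord:
    """A dated fossil occurrence and its evaluation state."""

    species: str
    x: float
    y: float
    age_min_ka: float
    age_max_ka: float
    source: str = ""
    resolved_slices_ka: np.ndarray | None = None
    paleoclimate: dict | None = None          # at the headline slice
    mess: MessResult | None = None
    realized: bool | None = None
    classification: str | None = None

    def __post_init__(self):
        if self.age_min_ka > self.age_max_ka:
            raise ValueError("age_min must be <= age_max")

    @property
    def within_potential(self) -> bool | None:
        if self.classification is None:
            return None
        return self.classification in (WITHIN_REALIZED, WITHIN_POTENTIAL_ONLY)


@dataclass
class PhysiologyRecord:
    """Experimental thermal-tolerance data for one species."""

    species: str
    ct_max_c: float | None = None       # critical thermal maximum
    ct_min_c: float | None = None       # critical thermal minimum
    inc_low_c: float | None = None      # incubation range
    inc_high_c: float | None = None
    note: str = ""

    def __post_init__(self):
        if (self.ct_max_c is not None and self.ct_min_c is not None
                and not self.ct_min_c < self.ct_max_c):
            raise ValueError("CT_min must be below CT_max")
        if (self.inc_low_c is not None and self.inc_high_c is not None
                and self.inc_low_c > self.inc_high_c):
            raise ValueError("incubation low must be <= high")


def fossil_mess_by_slice(fossil: FossilRecord, potential: NicheEnvelope,
                         modern: ClimateGrid, glacial: ClimateGrid,
                         isotope: IsotopeSeries) -> pd.DataFrame:
    """Combined MESS of the fossil's cell climate vs the potential niche
    for every slice in its age window."""
    times = isotope.window_slices(fossil.age_min_ka, fossil.age_max_ka)
    if times.size == 0:
        raise OutOfWindowError("age window outside the modeled slices")
    idx = cell_index(np.array([[fossil.x, fossil.y]]), modern)[0]
    if idx < 0:
        raise DataGapError(f"fossil at ({fossil.x}, {fossil.y}) outside "
                           "the climate grid")
    rows = []
    for t in times:
        grid = interpolate_slice(modern, glacial, isotope, t)
        vec = {v: float(grid.var(v)[idx]) for v in potential.var_names}
        m = mess_combined(potential.bounds_dict(), vec,
                          reference="potential-niche bounds")
        rows.append({"time_ka": float(t), "combined": m.combined,
                     "cell_id": int(idx), "vector": vec, "mess": m})
    return pd.DataFrame(rows)


def resolve_age(fossil: FossilRecord, mess_by_slice: pd.DataFrame,
                tie_tol: float = 0.0) -> np.ndarray:
    """Best-compatible slice(s): the window slice(s) maximizing the
    combined MESS score; exact ties are all retained as equally likely."""
    best = mess_by_slice["combined"].max()
    hits = mess_by_slice.loc[
        mess_by_slice["combined"] >= best - tie_tol, "time_ka"]
    resolved = np.sort(hits.to_numpy(dtype=float))
    fossil.resolved_slices_ka = resolved
    return resolved


def classify_fossil(fossil: FossilRecord, reference_vectors: np.ndarray,
                    potential: NicheEnvelope, modern: ClimateGrid,
                    glacial: ClimateGrid,
                    isotope: IsotopeSeries) -> FossilRecord:
    """Resolve the fossil's age and classify it against the species'
    realized and potential niches.

    ``reference_vectors`` are the species' modern occurrence climates over
    the potential niche's variables (array, columns aligned with
    ``potential.var_names``).  When several slices resolve, the most
    favorable one (highest combined MESS) supplies the headline
    classification; all resolved slices are retained on the record.
    """
    table = fossil_mess_by_slice(fossil, potential, modern, glacial, isotope)
    resolve_age(fossil, table)
    best = table.loc[table["combined"].idxmax()]
    fossil.paleoclimate = best["vector"]
    fossil.mess = best["mess"]
    vec = np.array([best["vector"][v] for v in potential.var_names])
    in_pot = bool(potential.contains(vec))
    in_real = in_pot and realized_membership(reference_vectors, vec)
    fossil.realized = in_real
    if in_real:
        fossil.classification = WITHIN_REALIZED
    elif in_pot:
        fossil.classification = WITHIN_POTENTIAL_ONLY
    else:
        fossil.classification = OUTSIDE_POTENTIAL
    return fossil


def summarize(fossils: list) -> dict:
    """Per-species and pooled classification tables plus the per-variable
    deviation table.

    Returns a dict with:

    ``per_species`` — N, % within realized niche, % within potential niche
    (1-decimal rounding applied once, after aggregation);
    ``total`` — pooled counts and count-weighted percentages;
    ``deviations`` — for each variable on which at least one fossil scores
    negative: N, mean MESS, max (most negative) MESS, partitioned by the
    fossil's overall within/outside-potential status and pooled.
    """
    if not fossils:
        raise ValueError("no fossils to summarize")
    rows = [{"species": f.species,
             "realized": f.classification == WITHIN_REALIZED,
             "potential": f.within_potential}
            for f in fossils]
    df = pd.DataFrame(rows)
    per = (df.groupby("species")
             .agg(n_fossils=("realized", "size"),
                  pct_within_realized=("realized", "mean"),
                  pct_within_potential=("potential", "mean")))
    per["pct_within_realized"] = (100 * per["pct_within_realized"]).round(1)
    per["pct_within_potential"] = (100 * per["pct_within_potential"]).round(1)

    total = {"n_fossils": int(len(df)),
             "pct_within_realized": round(100 * df["realized"].mean(), 1),
             "pct_within_potential": round(100 * df["potential"].mean(), 1)}

    dev_rows = []
    for f in fossils:
        if f.mess is None:
            continue
        subset = ("within modern potential niche" if f.within_potential
                  else "outside modern potential niche")
        for v, s in zip(f.mess.var_names, f.mess.scores):
            if s < 0:
                dev_rows.append({"subset": subset, "variable": v,
                                 "score": float(s)})
    if dev_rows:
        ddf = pd.DataFrame(dev_rows)
        parts = []
        grouped_all = (ddf.groupby("variable")["score"]
                       .agg(n="size", mean_mess="mean", max_mess="min")
                       .reset_index())
        grouped_all.insert(0, "subset", "total")
        parts.append(grouped_all)
        for name, grp in ddf.groupby("subset"):
            g = (grp.groupby("variable")["score"]
                 .agg(n="size", mean_mess="mean", max_mess="min")
                 .reset_index())
            g.insert(0, "subset", name)
            parts.append(g)
        deviations = pd.concat(parts, ignore_index=True)
        deviations[["mean_mess", "max_mess"]] = (
            deviations[["mean_mess", "max_mess"]].round(1))
    else:
        deviations = pd.DataFrame(columns=["subset", "variable", "n",
                                           "mean_mess", "max_mess"])
    return {"per_species": per, "total": total, "deviations": deviations}


def pool_percentages(per_species: pd.DataFrame,
                     column: str = "pct_within_potential") -> float:
    """Count-weighted pooling of per-species percentages (the Total-row
    arithmetic of the per-species summary table)."""
    n = per_species["n_fossils"]
    return float((per_species[column] * n).sum() / n.sum())


def compare_physiology(envelopes_by_slice: list,
                       physiology: PhysiologyRecord) -> dict:
    """Congruence of physiological limits with the per-slice envelopes.

    CT_max is congruent iff it is at or above the highest warm-month
    maximum (BIO5 upper bound) across all slices; CT_min iff it is at or
    below the lowest cold-month minimum (BIO6 lower bound); the incubation
    interval iff it overlaps the warm-quarter (BIO10) envelope interval in
    every slice.  Missing fields are skipped with a note.
    """
    report = {"species": physiology.species, "notes": []}

    def bound(env, var, which):
        if var not in env.var_names:
            return None
        lo, up = env.bound(var)
        return lo if which == "lower" else up

    bio5_up = [bound(e, "BIO5", "upper") for e in envelopes_by_slice]
    bio6_lo = [bound(e, "BIO6", "lower") for e in envelopes_by_slice]
    bio10 = [(e.bound("BIO10") if "BIO10" in e.var_names else None)
             for e in envelopes_by_slice]

    if physiology.ct_max_c is None or any(b is None for b in bio5_up):
        report["ct_max_congruent"] = None
        report["notes"].append("CT_max or BIO5 unavailable")
    else:
        report["ct_max_congruent"] = bool(
            physiology.ct_max_c >= max(bio5_up))
    if physiology.ct_min_c is None or any(b is None for b in bio6_lo):
        report["ct_min_congruent"] = None
        report["notes"].append("CT_min or BIO6 unavailable")
    else:
        report["ct_min_congruent"] = bool(
            physiology.ct_min_c <= min(bio6_lo))
    if (physiology.inc_low_c is None or physiology.inc_high_c is None
            or any(b is None for b in bio10)):
        report["incubation_congruent"] = None
        report["notes"].append("incubation range or BIO10 unavailable")
    else:
        report["incubation_congruent"] = bool(all(
            physiology.inc_low_c <= up and physiology.inc_high_c >= lo
            for lo, up in bio10))
    return report


def read_fossils_csv(path) -> list:
    """Fossil reader: columns species, x, y, age_min_ka, age_max_ka
    [, source]."""
    df = pd.read_csv(path)
    return [FossilRecord(species=r.species, x=float(r.x), y=float(r.y),
                         age_min_ka=float(r.age_min_ka),
                         age_max_ka=float(r.age_max_ka),
                         source=str(getattr(r, "source", "")))
            for r in df.itertuples()]


def read_physiology_csv(path) -> list:
    """Physiology reader: columns species, ct_max_c, ct_min_c, inc_low_c,
    inc_high_c (blanks allowed)."""
    df = pd.read_csv(path)

    def val(r, c):
        v = getattr(r, c, None)
        return None if v is None or pd.isna(v) else float(v)

    return [PhysiologyRecord(species=r.species,
                             ct_max_c=val(r, "ct_max_c"),
                             ct_min_c=val(r, "ct_min_c"),
                             inc_low_c=val(r, "inc_low_c"),
                             inc_high_c=val(r, "inc_high_c"))
            for r in df.itertuples()]
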