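"""Merge a recent N_e trajectory with a distant one into a single demography.

The recent trajectory (IBD-based, generations ~4-50) and the distant one
(sequence-based, typically starting at a few hundred generations) leave a gap
that the merge bridges by policy: ``"hold"`` keeps the last recent size
constant across the gap; ``"geometric"`` interpolates log-size linearly in
log-generation between the two boundary values.  Output is piecewise
constant, written as a two-column linear CSV plus an epochs JSON suitable as
demography input for LD-based recombination-map inference.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .ne import NeTrajectory

__all__ = ["read_ne_csv", "write_ne_csv", "bridge_value", "merge_trajectories", "write_epochs_json"]

_GEN_NAMES = {"generation", "generations", "gen", "g", "time"}
_NE_NAMES = {"ne", "n_e", "size"}
_YEAR_NAMES = {"years", "year", "time_years"}


def read_ne_csv(path, generation_time: float | None = None) -> NeTrajectory:
    """Read a linear-timescale CSV (generation or years column + N_e column).

    A years column is accepted only with an explicit ``generation_time``.
    Rows are sorted ascending; duplicate times collapse keeping the last.
    """
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    gen_col = next((cols[c] for c in cols if c in _GEN_NAMES), None)
    year_col = next((cols[c] for c in cols if c in _YEAR_NAMES), None)
    ne_col = next((cols[c] for c in cols if c in _NE_NAMES), None)
    if ne_col is None:
        raise ValueError(f"no N_e column among {list(df.columns)}")
    if gen_col is not None:
        gens = pd.to_numeric(df[gen_col], errors="coerce")
    elif year_col is not None:
        if generation_time is None:
            raise ValueError("years column requires an explicit generation_time")
        gens = pd.to_numeric(df[year_col], errors="coerce") / generation_time
    else:
        raise ValueError(f"no generation/years column among {list(df.columns)}")
    ne = pd.to_numeric(df[ne_col], errors="coerce")
    if gens.isna().any() or ne.isna().any():
        bad = int(np.flatnonzero(gens.isna() | ne.isna())[0]) + 2  # header is line 1
        raise ValueError(f"non-numeric cell at data line {bad}")
    out = pd.DataFrame({"gen": gens, "ne": ne}).drop_duplicates("gen", keep="last").sort_values("gen")
    return NeTrajectory(generations=out["gen"].to_numpy(), ne=out["ne"].to_numpy())


def write_ne_csv(traj: NeTrajectory, path) -> None:
    pd.DataFrame({"generation": traj.generations, "ne": traj.ne}).to_csv(path, index=False)


def bridge_value(recent: NeTrajectory, distant: NeTrajectory, g: float, policy: str = "geometric") -> float:
    """Size inside the gap between the two trajectories, per bridge policy."""
    g_r, n_r = recent.generations[-1], recent.ne[-1]
    g_d, n_d = distant.generations[0], distant.ne[0]
    if not g_r < g < g_d:
        raise ValueError(f"generation {g} is not inside the gap ({g_r}, {g_d})")
    if policy == "hold":
        return float(n_r)
    if policy == "geometric":
        w = (np.log(g) - np.log(g_r)) / (np.log(g_d) - np.log(g_r))
        return float(np.exp((1 - w) * np.log(n_r) + w * np.log(n_d)))
    raise ValueError(f"unknown bridge policy {policy!r}")


def merge_trajectories(
    recent: NeTrajectory,
    distant: NeTrajectory,
    bridge: str = "geometric",
    gap_points: int = 16,
) -> NeTrajectory:
    """Concatenate recent and distant trajectories, filling the gap by policy.

    The gap is sampled at ``gap_points`` geometrically spaced knots (only the
    geometric bridge needs them; hold uses one).  The output restricted to
    either input's domain is identical to that input.
    """
    g_r = recent.generations[-1]
    g_d = distant.generations[0]
    if g_r >= g_d:
        raise ValueError(
            f"domains overlap: recent ends at generation {g_r}, distant starts at {g_d}"
        )
    if bridge == "hold":
        # the recent value persists across the gap; no extra knot needed
        gap_g = np.empty(0)
        gap_n = np.empty(0)
    elif bridge == "geometric":
        gap_g = np.exp(np.linspace(np.log(g_r), np.log(g_d), gap_points + 2))[1:-1]
        gap_n = np.asarray([bridge_value(recent, distant, g, "geometric") for g in gap_g])
    else:
        raise ValueError(f"unknown bridge policy {bridge!r}")
    gens = np.concatenate([recent.generations, gap_g, distant.generations])
    ne = np.concatenate([recent.ne, gap_n, distant.ne])
    return NeTrajectory(generations=gens, ne=ne)


def write_epochs_json(traj: NeTrajectory, path) -> None:
    """Epochs as {sizes, change_times}: size i applies from change_times[i]
    (generations before present) until the next change time."""
    with open(path, "w") as fh:
        json.dump(
            {"change_times": traj.generations.tolist(), "sizes": traj.ne.tolist()},
            fh,
            indent=1,
        )
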