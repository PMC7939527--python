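"""Differentially methylated region (DMR) calling.

A DMR is a run of at least ``min_probes`` significant CpGs, all shifted in
the same direction by more than ``min_delta``, in which consecutive member
probes lie within ``max_gap`` base pairs of each other (chain rule, the
default) — or, in span mode, in which the whole run spans at most
``max_gap`` bp.
"""

from __future__ import annotations

import warnings

import pandas as pd

REQUIRED = ("probe_id", "chrom", "pos", "delta_beta", "direction")


def call_dmrs(probes: pd.DataFrame, max_gap: int = 250, min_probes: int = 2,
              min_delta: float = 0.2, mode: str = "gap") -> pd.DataFrame:
    """Aggregate significant probes into DMRs.

    ``probes`` must hold one row per significant CpG with columns
    ``probe_id, chrom, pos, delta_beta, direction``; rows with
    |Δβ| <= ``min_delta`` are dropped.  Input is sorted by (chrom, pos)
    internally (with a warning when it was not); duplicate positions on a
    chromosome are an error.  Output rows give 1-based inclusive start/end
    (positions of the first and last member probe), probe count, direction
    and mean Δβ, sorted by (chrom, start).
    """
    if mode not in ("gap", "span"):
        raise ValueError("mode must be 'gap' or 'span'")
    missing = [c for c in REQUIRED if c not in probes.columns]
    if missing:
        raise ValueError(f"input is missing columns: {missing}")
    probes = probes[probes["delta_beta"].abs() > min_delta]
    if probes.empty:
        return _empty()
    if probes.duplicated(["chrom", "pos"]).any():
        raise ValueError("duplicate probe positions on a chromosome")
    sorted_probes = probes.sort_values(["chrom", "pos"], kind="mergesort")
    if not sorted_probes.index.equals(probes.index):
        warnings.warn("input probes were not position-sorted; sorting",
                      stacklevel=2)
    probes = sorted_probes.reset_index(drop=True)

    records = []
    for chrom, grp in probes.groupby("chrom", sort=True):
        for direction, sub in _direction_runs(grp):
            if mode == "gap":
                for run in _gap_runs(sub, max_gap):
                    if len(run) >= min_probes:
                        records.append(_record(chrom, direction, run))
            else:
                for run in _span_windows(sub, max_gap, min_probes):
                    records.append(_record(chrom, direction, run))
    if not records:
        return _empty()
    out = pd.DataFrame(records).sort_values(["chrom", "start"])
    return out.reset_index(drop=True)


def _empty() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["chrom", "start", "end", "n_probes", "direction",
                 "mean_delta_beta"]
    )


def _direction_runs(grp: pd.DataFrame):
    """Split a position-sorted chromosome group on direction changes."""
    start = 0
    dirs = grp["direction"].to_list()
    for i in range(1, len(grp) + 1):
        if i == len(grp) or dirs[i] != dirs[start]:
            yield dirs[start], grp.iloc[start:i]
            start = i


def _gap_runs(sub: pd.DataFrame, max_gap: int):
    """Maximal runs whose consecutive gaps are all <= max_gap."""
    pos = sub["pos"].to_numpy()
    start = 0
    for i in range(1, len(sub) + 1):
        if i == len(sub) or pos[i] - pos[i - 1] > max_gap:
            yield sub.iloc[start:i]
            start = i


def _span_windows(sub: pd.DataFrame, max_span: int, min_probes: int):
    """Maximal windows with total span <= max_span (not nested in another)."""
    pos = sub["pos"].to_numpy()
    prev_j = -1
    for i in range(len(sub)):
        j = i
        while j + 1 < len(sub) and pos[j + 1] - pos[i] <= max_span:
            j += 1
        if j > prev_j and j - i + 1 >= min_probes:
            yield sub.iloc[i:j + 1]
            prev_j = j


def _record(chrom, direction, run: pd.DataFrame) -> dict:
    return {
        "chrom": chrom,
        "start": int(run["pos"].iloc[0]),
        "end": int(run["pos"].iloc[-1]),
        "n_probes": len(run),
        "direction": direction,
        "mean_delta_beta": float(run["delta_beta"].mean()),
    }


def significant_probes(dmps: pd.DataFrame, manifest: pd.DataFrame,
                       q_threshold: float = 0.05,
                       use_stringent: bool = False) -> pd.DataFrame:
    """Join DMP results with manifest positions for DMR calling.

    "Significant" defaults to q < ``q_threshold`` (before the stringent
    filters); set ``use_stringent`` to require the full stringent pass.
    """
    mask = dmps["q"] < q_threshold
    if use_stringent:
        mask &= dmps["passes_stringent"]
    keep = dmps[mask]
    ann = manifest.set_index("probe_id").loc[keep.index]
    out = pd.DataFrame(
        {
            "probe_id": keep.index,
            "chrom": ann["chrom"].to_numpy(),
            "pos": ann["pos"].to_numpy(),
            "delta_beta": keep["delta_beta"].to_numpy(),
            "direction": keep["direction"].to_numpy(),
        }
    )
    return out.sort_values(["chrom", "pos"], kind="mergesort",
                           ignore_index=True)
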