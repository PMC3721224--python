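"""Chemogroup x phylogroup x site integration — the metabogenomic synthesis.

Once samples carry a chemogroup (metabolite profile cluster), a phylogroup
(DNA-barcode clade) and a collection site, this module cross-tabulates the
partitions, measures how site-specific the chemistry is (per-site modal-group
purity), quantifies agreement between partitions with Rand / adjusted Rand
indices, and lists nesting exceptions — chemogroups that straddle more than
one phylogroup, the individual plants whose chemistry disagrees with their
lineage.
"""

from __future__ import annotations

import csv
import logging
from typing import Mapping, Sequence

import pandas as pd
from sklearn.metrics import adjusted_rand_score, rand_score

__all__ = [
    "IntegrateError",
    "read_design",
    "write_assignment",
    "read_assignment",
    "crosstab",
    "site_purity",
    "partition_concordance",
    "nesting_check",
    "integration_report",
]

logger = logging.getLogger(__name__)


class IntegrateError(ValueError):
    """Raised for inconsistent or empty partition inputs."""


def read_design(path) -> pd.DataFrame:
    """Read a study design CSV: sample_id, site, depth_m, site_name."""
    design = pd.read_csv(path, dtype={"sample_id": str, "site": str})
    required = {"sample_id", "site"}
    if not required.issubset(design.columns):
        raise IntegrateError(f"{path}: design file needs columns {sorted(required)}")
    return design.set_index("sample_id")


def write_assignment(path, assignment: Mapping[str, str], column: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", column])
        for sid in assignment:
            writer.writerow([sid, assignment[sid]])


def read_assignment(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or len(header) < 2 or header[0] != "sample_id":
            raise IntegrateError(f"{path}: expected header sample_id,<label>")
        for row in reader:
            if len(row) >= 2:
                out[row[0]] = row[1]
    return out


def _shared_ids(partitions: Sequence[Mapping[str, str]]) -> list[str]:
    shared = set(partitions[0])
    for p in partitions[1:]:
        shared &= set(p)
    dropped = set().union(*partitions) - shared
    if dropped:
        logger.info("dropping %d sample(s) absent from some partition: %s",
                    len(dropped), sorted(dropped))
    if not shared:
        raise IntegrateError("partitions share no sample ids")
    return sorted(shared)


def crosstab(partitions: Mapping[str, Mapping[str, str]]) -> pd.DataFrame:
    """Contingency counts over two or three named partitions.

    Only samples present in every partition are counted (dropped ids are
    logged).  Rows/columns are ordered by label so the table is deterministic.
    """
    if not 2 <= len(partitions) <= 3:
        raise IntegrateError("crosstab takes two or three partitions")
    names = list(partitions)
    shared = _shared_ids(list(partitions.values()))
    frame = pd.DataFrame(
        {name: [partitions[name][sid] for sid in shared] for name in names},
        index=shared,
    )
    table = pd.crosstab(
        frame[names[0]], [frame[n] for n in names[1:]], dropna=False
    ).sort_index(axis=0).sort_index(axis=1)
    return table


def site_purity(
    chemogroups: Mapping[str, str], sites: Mapping[str, str]
) -> dict[str, float]:
    """Per-site fraction of samples in the site's modal chemogroup."""
    shared = _shared_ids([chemogroups, sites])
    purity: dict[str, float] = {}
    for site in sorted({sites[s] for s in shared}):
        members = [s for s in shared if sites[s] == site]
        counts = pd.Series([chemogroups[s] for s in members]).value_counts()
        purity[site] = float(counts.iloc[0]) / len(members)
    return purity


def partition_concordance(
    p1: Mapping[str, str], p2: Mapping[str, str]
) -> dict[str, float]:
    """Rand and adjusted Rand indices between two partitions of the same samples."""
    shared = _shared_ids([p1, p2])
    if len(shared) < 2:
        raise IntegrateError("need at least two shared samples")
    a = [p1[s] for s in shared]
    b = [p2[s] for s in shared]
    return {
        "n_shared": len(shared),
        "rand": float(rand_score(a, b)),
        "adjusted_rand": float(adjusted_rand_score(a, b)),
    }


def nesting_check(
    chemogroups: Mapping[str, str], phylogroups: Mapping[str, str]
) -> list[dict]:
    """Chemogroups spanning more than one phylogroup, with offending members.

    A perfectly nested study returns an empty list; each exception names the
    chemogroup, the phylogroups it straddles, and the minority members (the
    samples not in the chemogroup's modal phylogroup).
    """
    shared = _shared_ids([chemogroups, phylogroups])
    exceptions = []
    for cg in sorted({chemogroups[s] for s in shared}):
        members = [s for s in shared if chemogroups[s] == cg]
        span = sorted({phylogroups[s] for s in members})
        if len(span) > 1:
            counts = pd.Series([phylogroups[s] for s in members]).value_counts()
            modal = counts.index[0]
            exceptions.append(
                {
                    "chemogroup": cg,
                    "phylogroups": span,
                    "minority_members": sorted(
                        s for s in members if phylogroups[s] != modal
                    ),
                }
            )
    return exceptions


def integration_report(
    chemogroups: Mapping[str, str],
    phylogroups_by_marker: Mapping[str, Mapping[str, str]],
    design: pd.DataFrame | None = None,
) -> dict:
    """Full metabogenomic report: crosstabs, purities, concordance, exceptions.

    Samples covered chemically but not genetically stay in chemogroup-only
    statistics and are dropped pairwise elsewhere; coverage counts make the
    difference explicit.
    """
    report: dict = {
        "coverage": {
            "chemogroups": len(chemogroups),
            **{m: len(p) for m, p in phylogroups_by_marker.items()},
        },
        "chemogroup_sizes": {
            cg: sorted(s for s in chemogroups if chemogroups[s] == cg)
            for cg in sorted(set(chemogroups.values()))
        },
        "markers": {},
    }
    sites = None
    if design is not None:
        sites = {str(sid): str(row["site"]) for sid, row in design.iterrows()}
        report["site_purity"] = site_purity(chemogroups, sites)
        report["chemogroup_by_site"] = (
            crosstab({"chemogroup": chemogroups, "site": sites})
            .to_dict()
        )
        report["site_metadata"] = {
            str(row["site"]): {
                k: row[k] for k in ("depth_m", "site_name") if k in design.columns
            }
            for _, row in design.reset_index().iterrows()
        }
    for marker, pg in phylogroups_by_marker.items():
        entry: dict = {
            "concordance_chemo": partition_concordance(chemogroups, pg),
            "nesting_exceptions": nesting_check(chemogroups, pg),
            "crosstab_chemo": crosstab({"chemogroup": chemogroups, "phylogroup": pg}).to_dict(),
        }
        if sites is not None:
            entry["concordance_site"] = partition_concordance(pg, sites)
        report["markers"][marker] = entry
    markers = list(phylogroups_by_marker)
    if len(markers) >= 2:
        conflicts = {}
        for m1, m2 in zip(markers, markers[1:]):
            a, b = phylogroups_by_marker[m1], phylogroups_by_marker[m2]
            shared = sorted(set(a) & set(b))
            conc = partition_concordance(a, b)
            # samples whose group differs between markers, up to relabeling
            ct = crosstab({m1: a, m2: b})
            disagree = []
            for sid in shared:
                row_modal = ct.loc[a[sid]].idxmax()
                if b[sid] != row_modal:
                    disagree.append(sid)
            conflicts[f"{m1}_vs_{m2}"] = {
                "concordance": conc,
                "conflicting_samples": disagree,
            }
        report["cross_marker"] = conflicts
    return report
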