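"""The Palmer Station study design and its reported group structure.

The motivating dataset is a seven-site survey of the red alga *Plocamium
cartilagineum* around Palmer Station (Anvers Island, Antarctica): three
individual plants per site, 21 samples in all, labelled by site number (1-7)
and replicate letter (A-C).  The raw chromatograms and per-sample sequences
are not distributed, but the reported group memberships and the similarity
levels at which the groups merge are, which is enough to reconstruct the
ultrametric skeleton of the study's Bray-Curtis dendrogram and its
chemogroup / phylogroup / site structure.  These fixtures serve as reference
inputs for the integration statistics and as the template the synthetic-data
generator emulates.

Reconstructed structure (similarity levels in % Bray-Curtis):

* five chemogroups delineated above 50% similarity;
* within a collection site, replicates cluster above 70%;
* chemogroups 2 and 4 merge at ~40%, chemogroup 3 joins them at ~30%,
  chemogroup 5 joins that cluster at ~30%, and chemogroup 1 is the outgroup
  at ~10%;
* two phylogroups: A = chemogroups 1 and 5, B = chemogroups 2, 3 and 4;
* site exceptions: sample 1B groups chemically with Hero Inlet plants (CG2)
  and 6C with Old Palmer plants (CG5); sample 6A switches phylogroup between
  the cox1 and rbcL markers.

Exact leaf order inside groups is not recoverable; everything downstream is
invariant to it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "SITE_DEPTHS_M",
    "SITE_NAMES",
    "sample_ids",
    "site_assignments",
    "chemogroup_assignments",
    "phylogroup_assignments",
    "chemogroup_to_phylogroup",
    "study_design",
    "study_similarity_matrix",
]

SITE_DEPTHS_M: dict[str, int] = {"1": 19, "2": 10, "3": 6, "4": 4, "5": 17, "6": 6, "7": 12}

SITE_NAMES: dict[str, str] = {
    "1": "Hermit Island",
    "2": "Norsel Point wall",
    "3": "Norsel Point cove",
    "4": "Old Palmer Station",
    "5": "Bahia Paraiso shipwreck",
    "6": "Hero Inlet",
    "7": "Litchfield Island",
}

#: base chemogroup of each site; two single-sample exceptions override it
_SITE_CHEMOGROUP = {"1": "CG1", "2": "CG1", "3": "CG3", "4": "CG5", "5": "CG4", "6": "CG2", "7": "CG3"}
_CHEMO_EXCEPTIONS = {"1B": "CG2", "6C": "CG5"}

#: phylogroup of each chemogroup (cox1 view); rbcL flips sample 6A to A
_CG_PHYLOGROUP = {"CG1": "A", "CG2": "B", "CG3": "B", "CG4": "B", "CG5": "A"}
_RBCL_EXCEPTIONS = {"6A": "A"}

#: similarity (%) at which chemogroup clusters merge, as an ultrametric on groups
_GROUP_MERGE_SIMILARITY = {
    frozenset({"CG2", "CG4"}): 40.0,
    frozenset({"CG2", "CG3"}): 30.0,
    frozenset({"CG3", "CG4"}): 30.0,
    frozenset({"CG2", "CG5"}): 30.0,
    frozenset({"CG3", "CG5"}): 30.0,
    frozenset({"CG4", "CG5"}): 30.0,
    frozenset({"CG1", "CG2"}): 10.0,
    frozenset({"CG1", "CG3"}): 10.0,
    frozenset({"CG1", "CG4"}): 10.0,
    frozenset({"CG1", "CG5"}): 10.0,
}


def sample_ids() -> list[str]:
    """The 21 sample ids, 1A .. 7C."""
    return [f"{site}{rep}" for site in "1234567" for rep in "ABC"]


def site_assignments() -> dict[str, str]:
    return {sid: sid[0] for sid in sample_ids()}


def chemogroup_assignments() -> dict[str, str]:
    """Sample -> chemogroup, with the 1B and 6C exceptions applied."""
    return {
        sid: _CHEMO_EXCEPTIONS.get(sid, _SITE_CHEMOGROUP[sid[0]]) for sid in sample_ids()
    }


def chemogroup_to_phylogroup() -> dict[str, str]:
    return dict(_CG_PHYLOGROUP)


def phylogroup_assignments(marker: str = "cox1") -> dict[str, str]:
    """Sample -> phylogroup under one marker (rbcL moves 6A into group A)."""
    chemo = chemogroup_assignments()
    labels = {sid: _CG_PHYLOGROUP[chemo[sid]] for sid in sample_ids()}
    if marker == "rbcL":
        labels.update(_RBCL_EXCEPTIONS)
    elif marker != "cox1":
        raise ValueError(f"unknown marker {marker!r}")
    return labels


def study_design() -> pd.DataFrame:
    """Design table: sample_id (index), site, depth_m, site_name."""
    rows = [
        {
            "sample_id": sid,
            "site": sid[0],
            "depth_m": SITE_DEPTHS_M[sid[0]],
            "site_name": SITE_NAMES[sid[0]],
        }
        for sid in sample_ids()
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def study_similarity_matrix(
    within_site: float = 75.0, within_chemogroup: float = 60.0
) -> pd.DataFrame:
    """Ultrametric Bray-Curtis dissimilarity over the 21 samples.

    Cophenetic similarity between two samples is the merge level of the
    smallest cluster containing both: ``within_site`` (%) for same-site
    replicates of the same chemogroup, ``within_chemogroup`` for same-group
    samples from different sites, and the reconstructed group-merge levels
    otherwise.  ``within_site`` defaults to 75 (the study reports site
    cohesion above 70%) and the cross-site level sits between the 50% group
    cut and the site level.  Returned as dissimilarity in [0, 1].
    """
    ids = sample_ids()
    chemo = chemogroup_assignments()
    d = np.zeros((len(ids), len(ids)))
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            b = ids[j]
            if chemo[a] == chemo[b]:
                sim = within_site if a[0] == b[0] else within_chemogroup
            else:
                sim = _GROUP_MERGE_SIMILARITY[frozenset({chemo[a], chemo[b]})]
            d[i, j] = d[j, i] = 1.0 - sim / 100.0
    return pd.DataFrame(d, index=ids, columns=ids)
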