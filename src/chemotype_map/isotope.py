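"""Halogen isotopologue envelopes for GC/MS annotation of polyhalogenated metabolites.

Chlorine and bromine each occur as two stable isotopes two mass units apart
(35/37Cl and 79/81Br), so a molecular ion carrying several such atoms appears
in a mass spectrum as a cluster of peaks at 2 amu spacing whose relative
heights follow the product of two binomial distributions.  The cluster shape
therefore encodes the halogen count: one Br gives a near 1:1 doublet, two Br
the familiar ~1:2:1 triplet, mixed Cl/Br compositions their own signatures.
Matching an observed cluster against the theoretical envelopes of all
(n_Cl, n_Br) compositions up to a search bound identifies polyhalogenated
ions — the signature used to recognise the halogenated monoterpenes of
*Plocamium cartilagineum* in negative-chemical-ionization GC/MS data.

The model is halogen-only by default: 13C and 2H contributions are ignored,
which is adequate at nominal (unit) mass resolution where the Cl/Br pattern
dominates.  An optional carbon count adds 13C shoulders between the 2 amu
peaks for sensitivity checks.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CL_ABUNDANCE",
    "BR_ABUNDANCE",
    "C13_ABUNDANCE",
    "ISOTOPE_SPACING_AMU",
    "EnvelopeError",
    "HalogenComposition",
    "IsotopeEnvelope",
    "HalogenHypothesis",
    "theoretical_envelope",
    "envelope_similarity",
    "infer_halogens",
    "classify_polyhalogenated",
    "read_envelope_csv",
    "write_envelope_csv",
    "annotate_envelopes",
]

#: natural isotopic abundances as (light, heavy) fractions
CL_ABUNDANCE: tuple[float, float] = (0.7576, 0.2424)
BR_ABUNDANCE: tuple[float, float] = (0.5069, 0.4931)
#: (12C, 13C) — used only when a carbon count is supplied explicitly
C13_ABUNDANCE: tuple[float, float] = (0.9893, 0.0107)

#: nominal mass gap between adjacent Cl/Br isotopologues
ISOTOPE_SPACING_AMU: float = 2.0


class EnvelopeError(ValueError):
    """Raised for envelopes or halogen compositions outside the model's domain."""


@dataclass(frozen=True)
class HalogenComposition:
    """A hypothesised elemental composition of exchangeable halogens.

    Parameters
    ----------
    n_cl, n_br
        Number of chlorine and bromine atoms; both must be non-negative.
    """

    n_cl: int
    n_br: int

    def __post_init__(self) -> None:
        if self.n_cl < 0 or self.n_br < 0:
            raise EnvelopeError(
                f"halogen counts must be non-negative, got n_cl={self.n_cl}, n_br={self.n_br}"
            )

    @property
    def total(self) -> int:
        return self.n_cl + self.n_br

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"Cl{self.n_cl}Br{self.n_br}"


@dataclass
class IsotopeEnvelope:
    """An ordered series of isotopologue abundances at fixed mass spacing.

    ``abundances[0]`` is the lightest isotopologue.  Theoretical envelopes are
    normalised to a first peak of 1; observed envelopes may arrive in any
    positive scale (similarity scoring is scale-invariant).
    """

    abundances: np.ndarray
    spacing_amu: float = ISOTOPE_SPACING_AMU
    base_mass: float | None = None
    normalization: str = "none"

    def __post_init__(self) -> None:
        a = np.asarray(self.abundances, dtype=float).ravel()
        if a.size == 0:
            raise EnvelopeError("envelope must contain at least one abundance")
        if not np.all(np.isfinite(a)) or np.any(a < 0):
            raise EnvelopeError("abundances must be finite and non-negative")
        if not np.any(a > 0):
            raise EnvelopeError("envelope is all-zero")
        self.abundances = a

    def __len__(self) -> int:
        return int(self.abundances.size)

    def normalized(self, mode: str = "first") -> "IsotopeEnvelope":
        """Return a copy rescaled so the first (or maximum) abundance equals 1."""
        if mode == "first":
            if self.abundances[0] <= 0:
                raise EnvelopeError("cannot normalise to a zero first peak")
            scale = self.abundances[0]
        elif mode == "max":
            scale = self.abundances.max()
        else:
            raise EnvelopeError(f"unknown normalization mode {mode!r}")
        return IsotopeEnvelope(
            self.abundances / scale,
            spacing_amu=self.spacing_amu,
            base_mass=self.base_mass,
            normalization=mode,
        )


@dataclass(frozen=True)
class HalogenHypothesis:
    """One candidate halogen composition with its envelope-match score."""

    composition: HalogenComposition
    score: float
    rank: int


def _coerce_composition(comp) -> HalogenComposition:
    if isinstance(comp, HalogenComposition):
        return comp
    n_cl, n_br = comp
    return HalogenComposition(int(n_cl), int(n_br))


def theoretical_envelope(
    comp,
    *,
    cl_abundance: tuple[float, float] = CL_ABUNDANCE,
    br_abundance: tuple[float, float] = BR_ABUNDANCE,
    n_carbon: int = 0,
    base_mass: float | None = None,
) -> IsotopeEnvelope:
    """Predict the isotopologue envelope of ``n_cl`` Cl and ``n_br`` Br atoms.

    The abundance polynomial of each atom is convolved (equivalently, the
    binomial distributions are multiplied), and the result is normalised to a
    lightest peak of 1.  Length is ``n_cl + n_br + 1`` in the halogen-only
    model.  With ``n_carbon > 0`` the 13C binomial is folded in at 1 amu
    resolution, producing shoulders between the 2 amu halogen peaks; the peaks
    are then reported at 1 amu spacing.
    """
    comp = _coerce_composition(comp)
    env = np.array([1.0])
    for _ in range(comp.n_cl):
        env = np.convolve(env, np.asarray(cl_abundance))
    for _ in range(comp.n_br):
        env = np.convolve(env, np.asarray(br_abundance))
    spacing = ISOTOPE_SPACING_AMU
    if n_carbon:
        if n_carbon < 0:
            raise EnvelopeError("carbon count must be non-negative")
        # interleave the 2 amu halogen comb with zeros, then fold in 13C at 1 amu
        fine = np.zeros(2 * env.size - 1)
        fine[::2] = env
        for _ in range(n_carbon):
            fine = np.convolve(fine, np.asarray(C13_ABUNDANCE))
        env = fine
        spacing = 1.0
    return IsotopeEnvelope(
        env / env[0], spacing_amu=spacing, base_mass=base_mass, normalization="first"
    )


def _padded_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = max(a.size, b.size)
    if a.size < n:
        a = np.pad(a, (0, n - a.size))
    if b.size < n:
        b = np.pad(b, (0, n - b.size))
    return a, b


def envelope_similarity(observed: IsotopeEnvelope, theoretical: IsotopeEnvelope) -> float:
    """Cosine similarity of two abundance vectors, zero-padding the shorter.

    Equals 1 iff the vectors are proportional, is invariant to positive
    rescaling of either argument, and lies in [0, 1] for non-negative
    abundances.
    """
    x, y = _padded_pair(observed.abundances, theoretical.abundances)
    if x.max() == 0 or y.max() == 0:
        raise EnvelopeError("cannot score an all-zero envelope")
    # pre-scale by the maximum so tiny abundances cannot underflow the norm
    x = x / x.max()
    y = y / y.max()
    return float(np.clip(np.dot(x, y) / (np.linalg.norm(x) * np.linalg.norm(y)), 0.0, 1.0))


def infer_halogens(observed: IsotopeEnvelope, max_total: int = 8) -> list[HalogenHypothesis]:
    """Rank every halogen composition with ``n_cl + n_br <= max_total``.

    Each composition is scored by :func:`envelope_similarity` between the
    observed envelope and its theoretical envelope.  The ranking is sorted by
    score descending; exact ties are broken deterministically in favour of
    fewer total halogens, then more chlorines.  Compositions whose envelope is
    shorter than the observed one are still scored (via zero padding) but
    cannot outrank an exact-length proportional match.
    """
    if max_total < 1:
        raise EnvelopeError("max_total must be at least 1")
    scored: list[tuple[float, int, int, HalogenComposition]] = []
    for n_cl, n_br in itertools.product(range(max_total + 1), repeat=2):
        if n_cl + n_br > max_total:
            continue
        comp = HalogenComposition(n_cl, n_br)
        score = envelope_similarity(observed, theoretical_envelope(comp))
        scored.append((-score, comp.total, -comp.n_cl, comp))
    scored.sort(key=lambda t: t[:3])
    return [
        HalogenHypothesis(composition=comp, score=-neg, rank=i + 1)
        for i, (neg, _, _, comp) in enumerate(scored)
    ]


def classify_polyhalogenated(
    observed: IsotopeEnvelope,
    min_halogens: int = 2,
    min_score: float = 0.95,
    max_total: int = 8,
) -> tuple[bool, HalogenHypothesis]:
    """Decide whether an envelope looks polyhalogenated.

    True iff the best-ranked composition carries at least ``min_halogens``
    halogen atoms and matches with at least ``min_score`` cosine similarity.
    Returns the decision together with the best hypothesis.
    """
    best = infer_halogens(observed, max_total=max_total)[0]
    verdict = best.composition.total >= min_halogens and best.score >= min_score
    return verdict, best


# ---------------------------------------------------------------------------
# envelope table I/O


def read_envelope_csv(path) -> list[tuple[str, IsotopeEnvelope]]:
    """Read envelopes from CSV with columns feature_id, base_mass, spacing, abundances.

    ``abundances`` is a semicolon-joined list (``a0;a1;...``).  ``feature_id``
    may be omitted, in which case rows are numbered f1, f2, ...
    """
    entries: list[tuple[str, IsotopeEnvelope]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise EnvelopeError(f"{path}: empty envelope file")
        for i, row in enumerate(reader, start=2):
            try:
                abund = [float(v) for v in row["abundances"].split(";") if v != ""]
                base = row.get("base_mass") or None
                spacing = row.get("spacing") or ISOTOPE_SPACING_AMU
                env = IsotopeEnvelope(
                    np.asarray(abund),
                    spacing_amu=float(spacing),
                    base_mass=float(base) if base else None,
                )
            except (KeyError, ValueError) as exc:
                raise EnvelopeError(f"{path}: malformed envelope row at line {i}: {exc}") from exc
            entries.append((row.get("feature_id") or f"f{i - 1}", env))
    return entries


def write_envelope_csv(path, entries: Iterable[tuple[str, IsotopeEnvelope]]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["feature_id", "base_mass", "spacing", "abundances"])
        for fid, env in entries:
            writer.writerow(
                [
                    fid,
                    "" if env.base_mass is None else env.base_mass,
                    env.spacing_amu,
                    ";".join(repr(float(a)) for a in env.abundances),
                ]
            )


def annotate_envelopes(
    entries: Sequence[tuple[str, IsotopeEnvelope]],
    max_total: int = 8,
    min_halogens: int = 2,
    min_score: float = 0.95,
) -> list[dict]:
    """Classify each (feature_id, envelope) pair; returns JSON-ready records."""
    records = []
    for fid, env in entries:
        verdict, best = classify_polyhalogenated(
            env, min_halogens=min_halogens, min_score=min_score, max_total=max_total
        )
        records.append(
            {
                "feature_id": fid,
                "best_n_cl": best.composition.n_cl,
                "best_n_br": best.composition.n_br,
                "score": best.score,
                "polyhalogenated": verdict,
            }
        )
    return records
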