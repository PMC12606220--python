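"""Peptide-mass-fingerprint screening: marker matching, taxon assignment,
preservation class and the deamidation index.

A marker panel maps each taxon to a set of diagnostic peptide m/z values.
Because collagen is highly conserved, some taxa cannot be separated by their
markers at all; those form *ambiguity groups* and a sample matching only the
shared markers is assigned the group label (e.g. a wallaby/pademelon pair)
rather than a single taxon.

Collagen preservation is scored from the visibility of high-m/z peaks, and
collagen degradation is indexed by the intensity ratio of the nominal
1105/1106 peak pair (glutamine deamidation shifts intensity from 1105.58 to
1106.56; lower ratios mean more deamidation, i.e. more degraded collagen).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .peaks import PeakList

#: Nominal m/z of the non-deamidated / deamidated reference peak pair.
DEAMIDATION_REF_MZ = 1105.58
DEAMIDATION_DEAM_MZ = 1106.56


@dataclass
class MarkerPanel:
    """Diagnostic marker m/z values per taxon.

    ``markers`` maps taxon_id -> set of m/z values (Da); ``annotations`` may
    map (taxon_id, mz) -> peptide description.  ``ambiguity_groups`` are
    disjoint sets of taxa whose panels cannot separate them; they are
    reported under a joint label such as ``"A/B"``.
    """

    markers: dict[str, set[float]]
    annotations: dict[tuple[str, float], str] = field(default_factory=dict)
    ambiguity_groups: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for taxon, mzs in self.markers.items():
            for mz in mzs:
                if mz <= 0:
                    raise ValueError(f"{taxon}: non-positive marker m/z {mz}")
        seen: set[str] = set()
        for grp in self.ambiguity_groups:
            if seen & grp:
                raise ValueError("ambiguity groups must be disjoint")
            seen |= grp

    @property
    def taxa(self) -> list[str]:
        return list(self.markers)

    def group_of(self, taxon: str) -> frozenset[str]:
        for grp in self.ambiguity_groups:
            if taxon in grp:
                return grp
        return frozenset([taxon])

    @staticmethod
    def group_label(group: Iterable[str]) -> str:
        return "/".join(sorted(group))


@dataclass
class IdentificationResult:
    sample_id: str
    marker_counts: dict[str, int]
    assignment: str  # taxon_id, "A/B" group label, or "indeterminate"
    preservation_class: str  # "good" | "poor"
    deamidation_index: float | None  # None when either peak is absent


def match_peaks(
    obs: Sequence[float] | PeakList,
    theo: Sequence[float],
    tolerance: float = 0.2,
) -> list[tuple[int, int, float]]:
    """Greedy nearest-neighbour one-to-one matching of observed to
    theoretical m/z values.

    Candidate pairs within ``tolerance`` are taken in order of |Δm/z|; each
    observed and each theoretical peak is used at most once.  Returns
    (obs_index, theo_index, delta) triples, delta = obs − theo.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    obs_mz = obs.mz if isinstance(obs, PeakList) else np.asarray(obs, dtype=float)
    theo_mz = np.asarray(theo, dtype=float)
    if len(obs_mz) == 0 or len(theo_mz) == 0:
        return []
    candidates = []
    for i, om in enumerate(obs_mz):
        deltas = om - theo_mz
        for j in np.flatnonzero(np.abs(deltas) <= tolerance):
            candidates.append((abs(deltas[j]), i, int(j), deltas[j]))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used_obs: set[int] = set()
    used_theo: set[int] = set()
    matches = []
    for _, i, j, delta in candidates:
        if i in used_obs or j in used_theo:
            continue
        used_obs.add(i)
        used_theo.add(j)
        matches.append((i, j, float(delta)))
    matches.sort()
    return matches


def preservation_class(
    obs: PeakList,
    high_mz_threshold: float = 2400.0,
    min_high_peaks: int = 2,
    min_relative_intensity: float = 0.10,
) -> str:
    """Classify collagen preservation as "good" or "poor".

    "good" requires at least ``min_high_peaks`` peaks above
    ``high_mz_threshold`` whose intensity reaches ``min_relative_intensity``
    of the base peak — i.e. high-m/z peptides clearly visible.  An empty
    spectrum is "poor".
    """
    if high_mz_threshold <= 0 or min_high_peaks <= 0 or min_relative_intensity <= 0:
        raise ValueError("thresholds must be positive")
    if len(obs) == 0:
        return "poor"
    floor = min_relative_intensity * obs.base_peak_intensity
    n_high = sum(1 for mz, inten in obs.peaks if mz > high_mz_threshold and inten >= floor)
    return "good" if n_high >= min_high_peaks else "poor"


def deamidation_index(
    obs: PeakList,
    ref_mz: float = DEAMIDATION_REF_MZ,
    deam_mz: float = DEAMIDATION_DEAM_MZ,
    tolerance: float = 0.2,
) -> float | None:
    """Intensity ratio I(ref)/I(deam) of the 1105.58/1106.56 peak pair.

    Lower values indicate more deamidation (more degraded collagen).
    Returns None when either peak is absent within ``tolerance`` — absence is
    flagged, not reported as 0.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")

    def _nearest(target: float) -> float | None:
        best = None
        for mz, inten in obs.peaks:
            if abs(mz - target) <= tolerance:
                if best is None or abs(mz - target) < best[0]:
                    best = (abs(mz - target), inten)
        return None if best is None else best[1]

    ref_int = _nearest(ref_mz)
    deam_int = _nearest(deam_mz)
    if ref_int is None or deam_int is None or deam_int == 0:
        return None
    return ref_int / deam_int


def classify_taxon(
    obs: PeakList,
    panel: MarkerPanel,
    tolerance: float = 0.2,
    min_markers: int = 2,
) -> IdentificationResult:
    """Assign a sample to a taxon (or ambiguity group) from its fingerprint.

    Score per taxon = number of panel markers matched within ``tolerance``
    (one-to-one).  The unique top scorer is assigned when its score reaches
    ``min_markers`` and beats every taxon outside its ambiguity group; if the
    top scorers are exactly an ambiguity group (tied), the group label is
    returned; anything else is "indeterminate".
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if not panel.markers:
        raise ValueError("empty marker panel")
    counts: dict[str, int] = {}
    for taxon, mzs in panel.markers.items():
        counts[taxon] = len(match_peaks(obs, sorted(mzs), tolerance))

    best = max(counts.values(), default=0)
    top = [t for t, c in counts.items() if c == best]
    assignment = "indeterminate"
    if best >= min_markers:
        if len(top) == 1:
            taxon = top[0]
            group = panel.group_of(taxon)
            outside = [c for t, c in counts.items() if t not in group]
            if not outside or best > max(outside):
                assignment = taxon
        else:
            groups = {panel.group_of(t) for t in top}
            if len(groups) == 1 and set(top) == set(next(iter(groups))):
                group = next(iter(groups))
                outside = [c for t, c in counts.items() if t not in group]
                if not outside or best > max(outside):
                    assignment = MarkerPanel.group_label(group)
    return IdentificationResult(
        sample_id=obs.sample_id,
        marker_counts=counts,
        assignment=assignment,
        preservation_class=preservation_class(obs),
        deamidation_index=deamidation_index(obs),
    )


def build_marker_panel(
    fingerprints: Mapping[str, Sequence[float]],
    tolerance: float = 0.2,
    unique_only: bool = False,
) -> MarkerPanel:
    """Derive a marker panel from theoretical fingerprints.

    Collagen fingerprints are *collectively* unique: most peptides are shared
    between related taxa and identification rests on the joint peak pattern,
    so by default each taxon's panel is its full fingerprint — scoring then
    separates taxa by their substituted peptides.  With ``unique_only`` a
    panel keeps only peaks no other taxon possesses within ``tolerance``
    (classic single-marker style; sparse for closely related taxa).

    Taxa whose fingerprints are mutually indistinguishable at this tolerance
    are placed in an ambiguity group and reported under a joint label.
    """
    taxa = list(fingerprints)
    arrays = {t: np.sort(np.asarray(fingerprints[t], dtype=float)) for t in taxa}

    def _has_near(arr: np.ndarray, mz: float) -> bool:
        idx = np.searchsorted(arr, mz)
        for k in (idx - 1, idx):
            if 0 <= k < len(arr) and abs(arr[k] - mz) <= tolerance:
                return True
        return False

    # Pairwise distinguishability: can taxon a be told from taxon b?
    def _distinct(a: str, b: str) -> bool:
        return any(not _has_near(arrays[b], mz) for mz in arrays[a]) or any(
            not _has_near(arrays[a], mz) for mz in arrays[b]
        )

    # Union ambiguity groups of mutually indistinct taxa.
    groups: list[set[str]] = []
    for t in taxa:
        placed = False
        for grp in groups:
            if all(not _distinct(t, u) for u in grp):
                grp.add(t)
                placed = True
                break
        if not placed:
            groups.append({t})

    markers: dict[str, set[float]] = {}
    if unique_only:
        for grp in groups:
            others = [u for u in taxa if u not in grp]
            for t in grp:
                markers.setdefault(t, set())
                for mz in arrays[t]:
                    if all(not _has_near(arrays[u], mz) for u in others):
                        for member in grp:
                            if _has_near(arrays[member], mz):
                                markers.setdefault(member, set()).add(float(mz))
    else:
        markers = {t: {float(mz) for mz in arrays[t]} for t in taxa}
    ambiguity = [frozenset(g) for g in groups if len(g) > 1]
    return MarkerPanel(markers=markers, ambiguity_groups=ambiguity)


# ---------------------------------------------------------------------------
# Panel file I/O (TSV: taxon, mz, optional annotation; group rows optional).

def read_marker_panel(path: str | Path) -> MarkerPanel:
    markers: dict[str, set[float]] = {}
    annotations: dict[tuple[str, float], str] = {}
    groups: list[frozenset[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "ambiguity_group":
                groups.append(frozenset(parts[1].split(",")))
                continue
            if parts[0] == "taxon":  # header
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'taxon<TAB>mz'")
            taxon, mz = parts[0], float(parts[1])
            markers.setdefault(taxon, set()).add(mz)
            if len(parts) > 2 and parts[2]:
                annotations[(taxon, mz)] = parts[2]
    return MarkerPanel(markers=markers, annotations=annotations, ambiguity_groups=groups)


def write_marker_panel(panel: MarkerPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\tmz\tannotation\n")
        for taxon, mzs in panel.markers.items():
            for mz in sorted(mzs):
                ann = panel.annotations.get((taxon, mz), "")
                fh.write(f"{taxon}\t{mz:.4f}\t{ann}\n")
        for grp in panel.ambiguity_groups:
            fh.write(f"ambiguity_group\t{','.join(sorted(grp))}\n")
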