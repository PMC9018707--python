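"""Within-population haplotype-extension statistics.

Extended haplotype homozygosity (EHH) around a core SNP measures the
probability that two randomly drawn haplotypes carrying a given core allele
are identical over the whole interval from the core out to a marker ``x``.
Under neutrality EHH decays quickly with distance; around a recently
selected allele the decay is slow.  Integrating the decay curve over
physical distance gives iHH; the log-ratio of the ancestral and derived
integrals is the (raw) iHS, which is then standardized within
derived-allele-frequency bins and mapped to a -log10 two-sided Gaussian
p-value (piHS) for significance calling.

EHH uses the unbiased pair-counting form

    EHH(x) = sum_h n_h (n_h - 1) / (n_c (n_c - 1)),

where ``n_h`` counts copies of each distinct haplotype spanning core..x
among the ``n_c`` carriers of the core allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import erfc

from .panel import MISSING, HaplotypePanel

ArmStop = Literal["cutoff", "chrom_end", "max_extension", "gap"]

SQRT2 = math.sqrt(2.0)

_STOP_LABELS: tuple[ArmStop, ...] = ("chrom_end", "cutoff", "max_extension", "gap")


class EHHError(ValueError):
    """Raised when EHH cannot be computed for a core/allele."""


# --------------------------------------------------------------------------- #
# EHH profile
# --------------------------------------------------------------------------- #
@dataclass
class EHHProfile:
    """EHH decay curve around one core SNP for one core allele.

    Each arm starts at the core itself (EHH = 1 there) and runs outward; the
    arrays are ordered from the core towards the telomere.  ``stop_*``
    records why each arm ended: the EHH cutoff was crossed, the chromosome
    ended, the extension limit was hit, or a gap limit was exceeded.
    """

    core_index: int
    core_allele: str
    core_pos: int
    n_carriers: int
    left_pos: np.ndarray
    left_ehh: np.ndarray
    right_pos: np.ndarray
    right_ehh: np.ndarray
    stop_left: ArmStop = "chrom_end"
    stop_right: ArmStop = "chrom_end"

    @property
    def truncated(self) -> tuple[bool, bool]:
        """Per arm: True when stopped by a limit rather than the cutoff."""
        return (self.stop_left != "cutoff", self.stop_right != "cutoff")

    @property
    def ihh(self) -> float:
        return integrate_ihh(self)


def integrate_ihh(profile: EHHProfile) -> float:
    """Trapezoidal integral of the EHH curve over bp, both arms summed.

    The segment in which EHH first crosses the cutoff is closed at the first
    sub-cutoff marker using its actual EHH value — no extrapolation beyond
    observed markers.  A profile with fewer than two carriers integrates to 0.
    """
    if profile.n_carriers < 2:
        return 0.0
    total = 0.0
    for pos, ehh in ((profile.left_pos, profile.left_ehh),
                     (profile.right_pos, profile.right_ehh)):
        if len(pos) >= 2:
            total += abs(float(np.trapezoid(ehh, pos)))
    return total


def _walk_arm(
    haplo: np.ndarray,
    rows: np.ndarray,
    positions: np.ndarray,
    core: int,
    stop: int,
    step: int,
    cutoff: float,
    max_extension_bp: float | None,
    max_gap_bp: float | None,
    stat: str,
    init_keys: np.ndarray | None = None,
    norm: float = 1.0,
) -> tuple[list[int], list[float], ArmStop]:
    """Walk outward from ``core`` (exclusive) to ``stop`` (exclusive).

    ``stat`` selects the homozygosity estimator applied to the refined
    haplotype partition at each marker: ``"pair"`` for the carrier
    pair-counting EHH form, ``"site"`` for the unbiased Tang-style
    homozygosity ``(n * sum f_k^2 - 1) / (n - 1)`` over all haplotypes.
    ``init_keys`` seeds the partition (the site form includes the core's own
    alleles); each emitted value is divided by ``norm`` before the cutoff
    test, so the site form can report homozygosity relative to the core.
    """
    if init_keys is None:
        seed_keys = np.zeros(len(rows), dtype=np.int64)
    else:
        _, seed_keys = np.unique(init_keys, return_inverse=True)
        seed_keys = seed_keys.astype(np.int64)
    n_pts, pos_arr, val_arr, why_code = _walk_kernel(
        haplo,
        np.asarray(rows, dtype=np.int64),
        int(core),
        int(stop),
        int(step),
        np.asarray(positions, dtype=np.int64),
        float(cutoff),
        -1.0 if max_extension_bp is None else float(max_extension_bp),
        -1.0 if max_gap_bp is None else float(max_gap_bp),
        stat == "pair",
        seed_keys,
        float(norm),
    )
    return (
        [int(p) for p in pos_arr[:n_pts]],
        [float(v) for v in val_arr[:n_pts]],
        _STOP_LABELS[why_code],
    )


@njit(cache=True)
def _walk_kernel(
    haplo,
    rows,
    core,
    stop,
    step,
    positions,
    cutoff,
    max_extension_bp,
    max_gap_bp,
    pair_mode,
    seed_keys,
    norm,
):  # pragma: no cover - exercised through _walk_arm
    n = rows.size
    max_steps = abs(stop - core)
    pos_out = np.empty(max_steps, dtype=np.int64)
    val_out = np.empty(max_steps, dtype=np.float64)
    keys = seed_keys.copy()
    remap = np.full(2 * n + 2, -1, dtype=np.int64)
    touched = np.empty(n, dtype=np.int64)
    counts = np.zeros(n + 1, dtype=np.int64)
    denom_pair = n * (n - 1)
    n_pts = 0
    prev_pos = positions[core]
    why = 0  # chrom_end
    j = core + step
    while j != stop:
        gap = positions[j] - prev_pos
        if gap < 0:
            gap = -gap
        if max_gap_bp >= 0 and gap > max_gap_bp:
            why = 3
            break
        ext = positions[j] - positions[core]
        if ext < 0:
            ext = -ext
        if max_extension_bp >= 0 and ext > max_extension_bp:
            why = 2
            break
        # refine the partition by the allele at marker j, relabelling keys
        # to compact ids in order of first appearance
        n_new = 0
        n_touched = 0
        for i in range(n):
            nk = 2 * keys[i] + haplo[rows[i], j]
            if remap[nk] < 0:
                remap[nk] = n_new
                touched[n_touched] = nk
                n_touched += 1
                n_new += 1
            keys[i] = remap[nk]
        for t in range(n_touched):
            remap[touched[t]] = -1
        for k in range(n_new):
            counts[k] = 0
        for i in range(n):
            counts[keys[i]] += 1
        if pair_mode:
            acc = 0.0
            for k in range(n_new):
                acc += counts[k] * (counts[k] - 1)
            value = acc / denom_pair
        else:
            acc = 0.0
            for k in range(n_new):
                acc += float(counts[k]) * counts[k]
            value = (acc / n - 1.0) / (n - 1)
        value /= norm
        pos_out[n_pts] = positions[j]
        val_out[n_pts] = value
        n_pts += 1
        if value < cutoff:
            why = 1
            break
        prev_pos = positions[j]
        j += step
    return n_pts, pos_out, val_out, why


def _resolve_core_allele(panel: HaplotypePanel, core_index: int, core_allele) -> tuple[int, str]:
    """Map 'ancestral'/'derived'/0/1 to an allele code and a label."""
    if core_allele in (0, 1):
        anc = panel.variants["ancestral"].iloc[core_index]
        if anc in ("a", "b"):
            derived_code = 1 if anc == "a" else 0
            label = "derived" if core_allele == derived_code else "ancestral"
        else:
            label = f"allele_{core_allele}"
        return int(core_allele), label
    if core_allele not in ("ancestral", "derived"):
        raise ValueError(f"core_allele must be 'ancestral', 'derived', 0 or 1; got {core_allele!r}")
    anc = panel.variants["ancestral"].iloc[core_index]
    if anc not in ("a", "b"):
        raise EHHError(
            f"ancestral state unknown for core {panel.variants['id'].iloc[core_index]!r}"
        )
    anc_code = 0 if anc == "a" else 1
    code = anc_code if core_allele == "ancestral" else 1 - anc_code
    return code, core_allele


def compute_ehh(
    panel: HaplotypePanel,
    core_index: int,
    core_allele,
    cutoff: float = 0.05,
    max_extension_bp: float | None = None,
    max_gap_bp: float | None = None,
) -> EHHProfile:
    """EHH decay profile for one core SNP and core allele.

    ``core_allele`` is ``"ancestral"``/``"derived"`` (requires a known
    ancestral state) or an explicit allele code 0/1.  Arms extend until EHH
    drops below ``cutoff``, the chromosome ends, or a limit is hit.
    """
    panel.require_phased()
    code, label = _resolve_core_allele(panel, core_index, core_allele)
    rows = np.flatnonzero(panel.haplo[:, core_index] == code)
    if len(rows) < 2:
        raise EHHError(
            f"core {panel.variants['id'].iloc[core_index]!r}: allele {label} has "
            f"{len(rows)} carrier(s); need >= 2"
        )
    positions = panel.variants["pos_bp"].to_numpy()
    lo, hi = panel.chrom_bounds(core_index)
    core_pos = int(positions[core_index])

    rp, re, why_r = _walk_arm(
        panel.haplo, rows, positions, core_index, hi, +1,
        cutoff, max_extension_bp, max_gap_bp, "pair",
    )
    lp, le, why_l = _walk_arm(
        panel.haplo, rows, positions, core_index, lo - 1, -1,
        cutoff, max_extension_bp, max_gap_bp, "pair",
    )
    return EHHProfile(
        core_index=core_index,
        core_allele=label,
        core_pos=core_pos,
        n_carriers=len(rows),
        left_pos=np.asarray([core_pos] + lp, dtype=np.int64),
        left_ehh=np.asarray([1.0] + le),
        right_pos=np.asarray([core_pos] + rp, dtype=np.int64),
        right_ehh=np.asarray([1.0] + re),
        stop_left=why_l,
        stop_right=why_r,
    )


# --------------------------------------------------------------------------- #
# piHS transform
# --------------------------------------------------------------------------- #
def pihs_transform(std_score):
    """-log10 two-sided Gaussian tail probability of a standardized score.

    Computes ``-log10(1 - 2|Phi(x) - 0.5|)``; the two-sided tail
    ``2 * Q(|x|)`` is evaluated directly as ``erfc(|x| / sqrt 2)`` so scores
    out to |x| ~ 8 (and far beyond) keep full accuracy instead of losing it
    to ``1 - Phi`` cancellation.  Symmetric in the sign of the input;
    0 maps to 0.
    """
    x = np.abs(np.asarray(std_score, dtype=float))
    with np.errstate(divide="ignore"):
        out = -np.log10(erfc(x / SQRT2))
    if np.ndim(std_score) == 0:
        return float(out)
    return out


# --------------------------------------------------------------------------- #
# Genome-wide iHS scan
# --------------------------------------------------------------------------- #
SCAN_COLUMNS = [
    "chrom", "pos_bp", "id", "freq_derived", "ihh_a", "ihh_d",
    "raw_ihs", "std_ihs", "pihs", "allele_class", "significant", "reason",
]


def scan_ihs(
    panel: HaplotypePanel,
    min_maf: float = 0.01,
    cutoff: float = 0.05,
    freq_bin: float = 0.025,
    max_extension_bp: float | None = None,
    max_gap_bp: float | None = None,
    threshold: float = 6.0,
    keep_truncated: bool = True,
) -> pd.DataFrame:
    """Genome-wide iHS scan over every eligible SNP of a phased panel.

    Per SNP with known ancestral state and MAF >= ``min_maf``:
    ``raw_ihs = ln(iHH_a / iHH_d)``, standardized to mean 0 / sd 1 within
    derived-allele-frequency bins of width ``freq_bin``, then transformed to
    piHS and flagged at ``pihs > threshold``.  Negative standardized scores
    mark extended *derived* haplotypes, positive scores extended *ancestral*
    ones.  Ineligible SNPs are emitted with null scores and a reason code.

    Raises ``EHHError`` when no SNP is eligible.
    """
    panel.require_phased()
    m = panel.n_variants
    derived_code = panel.derived_code()
    p_derived = panel.derived_freq()
    maf = panel.maf()
    positions = panel.variants["pos_bp"].to_numpy()

    # chromosome bounds per variant, computed once
    chrom_codes, chrom_first = pd.factorize(panel.variants["chrom"])
    starts = np.zeros(len(chrom_first), dtype=np.int64)
    stops = np.zeros(len(chrom_first), dtype=np.int64)
    for c in range(len(chrom_first)):
        idx = np.flatnonzero(chrom_codes == c)
        starts[c], stops[c] = idx[0], idx[-1] + 1

    ihh_a = np.full(m, np.nan)
    ihh_d = np.full(m, np.nan)
    raw = np.full(m, np.nan)
    reason = np.full(m, "ok", dtype=object)
    truncated_any = np.zeros(m, dtype=bool)

    for j in range(m):
        if derived_code[j] == MISSING:
            reason[j] = "ancestral_unknown"
            continue
        if not np.isfinite(maf[j]) or maf[j] < min_maf:
            reason[j] = "low_maf"
            continue
        lo, hi = starts[chrom_codes[j]], stops[chrom_codes[j]]
        vals = {}
        for allele_label, code in (("a", 1 - derived_code[j]), ("d", derived_code[j])):
            rows = np.flatnonzero(panel.haplo[:, j] == code)
            if len(rows) < 2:
                vals = None
                break
            rp, re_, why_r = _walk_arm(
                panel.haplo, rows, positions, j, hi, +1,
                cutoff, max_extension_bp, max_gap_bp, "pair",
            )
            lp, le_, why_l = _walk_arm(
                panel.haplo, rows, positions, j, lo - 1, -1,
                cutoff, max_extension_bp, max_gap_bp, "pair",
            )
            prof = EHHProfile(
                core_index=j, core_allele=allele_label, core_pos=int(positions[j]),
                n_carriers=len(rows),
                left_pos=np.asarray([positions[j]] + lp, dtype=np.int64),
                left_ehh=np.asarray([1.0] + le_),
                right_pos=np.asarray([positions[j]] + rp, dtype=np.int64),
                right_ehh=np.asarray([1.0] + re_),
                stop_left=why_l, stop_right=why_r,
            )
            vals[allele_label] = integrate_ihh(prof)
            truncated_any[j] |= why_l == "chrom_end" or why_r == "chrom_end"
        if vals is None:
            reason[j] = "few_carriers"
            continue
        ihh_a[j], ihh_d[j] = vals["a"], vals["d"]
        if ihh_a[j] <= 0 or ihh_d[j] <= 0:
            reason[j] = "zero_ihh"
            ihh_a[j] = ihh_a[j] if ihh_a[j] > 0 else np.nan
            ihh_d[j] = ihh_d[j] if ihh_d[j] > 0 else np.nan
            continue
        raw[j] = math.log(ihh_a[j] / ihh_d[j])

    if not keep_truncated:
        drop = truncated_any & (reason == "ok")
        raw[drop] = np.nan
        reason[drop] = "chrom_end"

    if not (reason == "ok").any():
        raise EHHError("no SNP eligible for iHS (check ancestral states and MAF)")

    std = standardize_by_frequency(raw, p_derived, freq_bin, reason)
    scan = pd.DataFrame(
        {
            "chrom": panel.variants["chrom"],
            "pos_bp": panel.variants["pos_bp"],
            "id": panel.variants["id"],
            "freq_derived": p_derived,
            "ihh_a": ihh_a,
            "ihh_d": ihh_d,
            "raw_ihs": raw,
            "std_ihs": std,
            "reason": reason,
        }
    )
    return call_significant(scan, threshold=threshold)


def standardize_by_frequency(
    raw: np.ndarray,
    freq: np.ndarray,
    freq_bin: float,
    reason: np.ndarray | None = None,
) -> np.ndarray:
    """Standardize raw scores to mean 0 / sd 1 within frequency bins.

    Bins partition [0, 1] with width ``freq_bin``; bins holding fewer than
    two scored SNPs (or with zero spread) yield NaN, annotated in ``reason``
    (modified in place) when given.
    """
    std = np.full(raw.shape, np.nan)
    scored = np.isfinite(raw) & np.isfinite(freq)
    if not scored.any():
        return std
    n_bins = max(1, int(math.ceil(1.0 / freq_bin)))
    bins = np.clip((freq[scored] / freq_bin).astype(int), 0, n_bins - 1)
    idx = np.flatnonzero(scored)
    for b in np.unique(bins):
        members = idx[bins == b]
        vals = raw[members]
        if len(members) < 2 or np.std(vals) == 0:
            if reason is not None:
                reason[members] = "small_bin"
            continue
        std[members] = (vals - vals.mean()) / vals.std(ddof=0)
    return std


def call_significant(scan: pd.DataFrame, threshold: float = 6.0) -> pd.DataFrame:
    """(Re)derive piHS, allele class and significance flags for a scan.

    Significance is strict: ``pihs > threshold``.  The allele class follows
    the sign convention (negative standardized score = extended derived
    haplotype, positive = ancestral); exactly-zero scores stay unclassified
    and are never significant.
    """
    scan = scan.copy()
    std = scan["std_ihs"].to_numpy(dtype=float)
    pihs = np.full(std.shape, np.nan)
    finite = np.isfinite(std)
    pihs[finite] = pihs_transform(std[finite])
    allele_class = np.full(std.shape, None, dtype=object)
    allele_class[finite & (std < 0)] = "derived"
    allele_class[finite & (std > 0)] = "ancestral"
    significant = np.zeros(std.shape, dtype=bool)
    significant[finite] = (pihs[finite] > threshold) & (std[finite] != 0)
    scan["pihs"] = pihs
    scan["allele_class"] = allele_class
    scan["significant"] = significant
    ordered = [c for c in SCAN_COLUMNS if c in scan.columns]
    return scan[ordered + [c for c in scan.columns if c not in ordered]]


# --------------------------------------------------------------------------- #
# Bifurcation trees
# --------------------------------------------------------------------------- #
@dataclass
class BifurcationNode:
    """One node of a haplotype bifurcation tree.

    ``count`` is the number of carrier haplotypes passing through the node;
    children are ordered allele-0 branch first, then allele-1.
    """

    marker_index: int | None
    allele: int | None
    count: int
    children: list["BifurcationNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["BifurcationNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out


def bifurcation_tree(
    panel: HaplotypePanel,
    core_index: int,
    core_allele,
    direction: Literal["left", "right"] = "right",
    max_markers: int = 20,
) -> BifurcationNode:
    """Haplotype bifurcation tree outward from a core allele.

    The root holds every carrier of the core allele; each level splits the
    current nodes by the allele at the next marker outward (allele-0 branch
    before allele-1).  ``max_markers`` beyond the chromosome end simply
    truncates at the end.  At least one carrier is required.
    """
    panel.require_phased()
    code, label = _resolve_core_allele(panel, core_index, core_allele)
    rows = np.flatnonzero(panel.haplo[:, core_index] == code)
    if len(rows) == 0:
        raise EHHError(
            f"core {panel.variants['id'].iloc[core_index]!r}: allele {label} "
            "has no carriers"
        )
    lo, hi = panel.chrom_bounds(core_index)
    step = 1 if direction == "right" else -1
    stop = hi if direction == "right" else lo - 1

    root = BifurcationNode(marker_index=core_index, allele=code, count=len(rows))
    frontier: list[tuple[BifurcationNode, np.ndarray]] = [(root, rows)]
    j = core_index + step
    taken = 0
    while j != stop and taken < max_markers:
        nxt: list[tuple[BifurcationNode, np.ndarray]] = []
        for node, members in frontier:
            col = panel.haplo[members, j]
            for allele in (0, 1):
                sub = members[col == allele]
                if len(sub) == 0:
                    continue
                child = BifurcationNode(marker_index=j, allele=allele, count=len(sub))
                node.children.append(child)
                nxt.append((child, sub))
        frontier = nxt
        j += step
        taken += 1
    return root
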