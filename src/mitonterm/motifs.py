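"""Cleavage-site windows, position frequency matrices and differential logos.

Windows span 20 residues of presequence (positions -20..-1) and 10 residues of
mature protein (+1..+10); the cleavage happens between -1 and +1 and is
printed as an arrow. Short presequences are padded with ``-`` on the left,
short mature regions on the right; pads never enter the counts.

The differential ("iceLogo"-style) representation subtracts a reference
amino-acid composition — the position-independent frequencies of the supplied
proteome — from the observed per-position frequencies and reports the result
in percentage points, with a per-cell one-sample proportion z-test. No
multiple-testing correction is applied across cells, matching the convention
of differential-logo tools.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import AMINO_ACIDS, ProteinRecord

PAD = "-"
DEFAULT_UP = 20
DEFAULT_DOWN = 10
#: Window positions, presequence side negative, mature side positive; no zero.
DEFAULT_ALPHA = 0.05
DEFAULT_FREQ_THRESHOLD = 0.20
CONSENSUS_POSITIONS = (-3, -2, -1, 1, 2)


def window_positions(up: int = DEFAULT_UP, down: int = DEFAULT_DOWN) -> list[int]:
    return list(range(-up, 0)) + list(range(1, down + 1))


class MotifProfile:
    """Residue x position matrices for a set of aligned cleavage windows.

    Attributes are pandas DataFrames indexed by the 20 amino acids with
    window positions as columns: ``counts``, ``frequencies`` and, after
    :func:`icelogo_diff`, ``difference`` (percentage points) and ``p_values``.
    ``n_per_position`` counts non-pad residues per column.
    """

    def __init__(self, counts: pd.DataFrame, n_windows: int):
        self.counts = counts
        self.n_windows = n_windows
        self.n_per_position = counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.frequencies = counts.div(self.n_per_position, axis=1)
        self.reference_frequencies: pd.Series | None = None
        self.difference: pd.DataFrame | None = None
        self.p_values: pd.DataFrame | None = None

    @property
    def positions(self) -> list[int]:
        return list(self.counts.columns)


def extract_window(
    sequence: str,
    mature_start: int,
    up: int = DEFAULT_UP,
    down: int = DEFAULT_DOWN,
) -> str:
    """Aligned cleavage window around a 1-based mature-start position.

    Positions -up..-1 are the last residues of the presequence, +1..+down the
    first residues of the mature protein; out-of-range positions are padded
    with '-'.
    """
    if not 1 <= mature_start <= len(sequence):
        raise ValueError(
            f"mature_start {mature_start} outside 1..{len(sequence)}"
        )
    left = sequence[max(0, mature_start - 1 - up): mature_start - 1]
    left = PAD * (up - len(left)) + left
    right = sequence[mature_start - 1: mature_start - 1 + down]
    right = right + PAD * (down - len(right))
    return left + right


def build_pfm(
    windows: Sequence[str],
    up: int = DEFAULT_UP,
    down: int = DEFAULT_DOWN,
) -> MotifProfile:
    """Position frequency matrix from equal-length aligned windows."""
    if not windows:
        raise ValueError("no windows supplied")
    width = up + down
    positions = window_positions(up, down)
    counts = pd.DataFrame(
        0, index=list(AMINO_ACIDS), columns=positions, dtype=float
    )
    for w in windows:
        if len(w) != width:
            raise ValueError(
                f"window {w!r} has length {len(w)}, expected {width}"
            )
        for pos, residue in zip(positions, w):
            if residue == PAD:
                continue
            if residue == "X":
                continue  # unknown residue: excluded like a pad
            counts.loc[residue, pos] += 1
    return MotifProfile(counts, n_windows=len(windows))


def reference_frequencies(
    proteins: Iterable[ProteinRecord],
) -> pd.Series:
    """Position-independent amino-acid frequencies of a proteome."""
    counts = {aa: 0 for aa in AMINO_ACIDS}
    total = 0
    for prot in proteins:
        for aa in prot.sequence:
            if aa in counts:
                counts[aa] += 1
                total += 1
    if total == 0:
        raise ValueError("empty proteome")
    return pd.Series({aa: c / total for aa, c in counts.items()})


def icelogo_diff(
    profile: MotifProfile,
    reference: Mapping[str, float] | pd.Series,
    alpha: float = DEFAULT_ALPHA,
) -> MotifProfile:
    """Attach reference-differential percentages and per-cell significance.

    ``difference[r, p] = (f_obs - f_ref) * 100`` and the p-value comes from a
    two-sided one-sample proportion z-test with variance
    ``f_ref * (1 - f_ref) / n_p``. Positions with no observations get NaN.
    """
    ref = pd.Series(reference).reindex(list(AMINO_ACIDS))
    if ref.isna().any():
        raise ValueError("reference must cover all 20 residues")
    if not np.isclose(ref.sum(), 1.0, atol=1e-6):
        raise ValueError(f"reference frequencies sum to {ref.sum():.4f}, not 1")

    diff = pd.DataFrame(index=profile.counts.index,
                        columns=profile.counts.columns, dtype=float)
    pvals = pd.DataFrame(index=profile.counts.index,
                         columns=profile.counts.columns, dtype=float)
    for pos in profile.positions:
        n = profile.n_per_position[pos]
        if n == 0:
            diff[pos] = np.nan
            pvals[pos] = np.nan
            continue
        f_obs = profile.frequencies[pos]
        diff[pos] = (f_obs - ref) * 100.0
        se = np.sqrt(ref * (1.0 - ref) / n)
        z = (f_obs - ref) / se
        pvals[pos] = 2.0 * stats.norm.sf(np.abs(z))
    profile.reference_frequencies = ref
    profile.difference = diff
    profile.p_values = pvals
    profile.alpha = alpha
    return profile


def consensus_string(
    profile: MotifProfile,
    freq_threshold: float = DEFAULT_FREQ_THRESHOLD,
    require_significant: bool = True,
    alpha: float = DEFAULT_ALPHA,
    positions: Sequence[int] = CONSENSUS_POSITIONS,
) -> str:
    """Consensus motif text with the cleavage arrow between -1 and +1.

    At each position, residues whose frequency reaches ``freq_threshold``
    (and whose reference differential is significant at ``alpha`` when
    ``require_significant``) are listed in decreasing frequency; a position
    with no qualifying residue prints 'X'. Example output:
    ``RX(F/Y)↓(S/A)(S/T)``.
    """
    if require_significant and profile.p_values is None:
        raise ValueError(
            "profile has no p-values; run icelogo_diff first or pass "
            "require_significant=False"
        )
    parts: list[str] = []
    for pos in positions:
        residues = consensus_residues(
            profile, pos, freq_threshold, require_significant, alpha
        )
        if not residues:
            parts.append("X")
        elif len(residues) == 1:
            parts.append(residues[0])
        else:
            parts.append("(" + "/".join(residues) + ")")
    arrow_at = sum(1 for p in positions if p < 0)
    return "".join(parts[:arrow_at]) + "↓" + "".join(parts[arrow_at:])


def consensus_residues(
    profile: MotifProfile,
    position: int,
    freq_threshold: float = DEFAULT_FREQ_THRESHOLD,
    require_significant: bool = True,
    alpha: float = DEFAULT_ALPHA,
) -> list[str]:
    """Residues qualifying for the consensus at one window position."""
    freqs = profile.frequencies[position]
    sel = freqs[freqs >= freq_threshold]
    if require_significant:
        pv = profile.p_values[position]
        sel = sel[[aa for aa in sel.index if pd.notna(pv[aa]) and pv[aa] < alpha]]
    return list(sel.sort_values(ascending=False).index)


def write_profile(profile: MotifProfile, prefix: str | Path) -> None:
    """Write counts/frequencies (and differences/p-values if present) as TSV."""
    prefix = Path(prefix)
    profile.counts.to_csv(f"{prefix}.counts.tsv", sep="\t")
    profile.frequencies.to_csv(f"{prefix}.frequencies.tsv", sep="\t")
    if profile.difference is not None:
        profile.difference.to_csv(f"{prefix}.difference.tsv", sep="\t")
        profile.p_values.to_csv(f"{prefix}.pvalues.tsv", sep="\t")
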