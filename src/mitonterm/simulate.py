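"""Forward simulation of presequence processing and N-terminome observation.

The generator emulates what a knockout-vs-wild-type N-terminal enrichment
experiment on isolated mitochondria sees, with full ground truth:

* a proteome in which mitochondrial proteins carry cleavable presequences
  (length ~ truncated normal, mean 43.3, range 7-117, enriched in R/S/A/L),
  cleaved by MPP at -2R, -3R or no-R sites,
* secondary processing: ICP55-like removal of one (occasionally two)
  destabilizing residues after MPP, or OCT1-like removal of a multi-residue
  stretch (also MPP-independently from position 2, emulating proteins whose
  short presequence is removed by OCT1 alone),
* knockout genotypes in which the corresponding step is blocked, shifting
  the dominant N-terminus back to the intermediate,
* digestion into N-terminal peptides ending at an arginine (ArgC-like at
  the C-terminal side; lysines are assumed dimethyl-blocked), and
* a mutant/wild-type abundance ratio per observed terminus with log-normal
  noise on the log2 scale, clipped to a reporting cap, with termini absent
  from one channel reported at the cap.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    ProteinRecord,
    QuantifiedPeptide,
    write_fasta,
    write_localization_table,
    write_peptide_table,
)

GENOTYPES = ("WT", "icp55", "oct1")

#: Approximate background amino-acid frequencies of a plant proteome.
BACKGROUND_FREQ = {
    "A": 0.063, "C": 0.018, "D": 0.054, "E": 0.067, "F": 0.044,
    "G": 0.064, "H": 0.023, "I": 0.053, "K": 0.064, "L": 0.096,
    "M": 0.025, "N": 0.043, "P": 0.048, "Q": 0.035, "R": 0.055,
    "S": 0.091, "T": 0.051, "V": 0.069, "W": 0.012, "Y": 0.029,
}

#: Presequence composition: R, S, A and L enriched >=1.5x over background,
#: the qualitative signature of mitochondrial targeting peptides.
PRESEQ_ENRICHMENT = {"R": 1.8, "S": 1.8, "A": 1.6, "L": 1.5}

#: Destabilizing residues planted at the intermediate N-terminus of
#: ICP55-substrate proteins (what the peptidase exists to remove).
ICP55_REMOVED_FIRST = ("F", "Y", "L", "I")
ICP55_REMOVED_FIRST_W = (0.5, 0.25, 0.15, 0.1)
ICP55_REMOVED_SECOND = ("C", "T", "N")

MPP_CLASSES = ("-3R", "-2R", "no-R")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Defaults reflect the composition of a real mitochondrial N-terminome:
    ~80% of observed proteins genuinely mitochondrial, ~20% of those without
    a cleavable presequence, about half of the processed proteins further
    trimmed by ICP55 and a few percent by OCT1.
    """

    n_proteins: int = 200
    fraction_mito: float = 0.8
    fraction_no_presequence: float = 0.2
    fraction_icp55_substrate: float = 0.5
    fraction_oct1_substrate: float = 0.04
    mpp_class_weights: tuple[float, float, float] = (0.5, 0.35, 0.15)
    preseq_mean: float = 43.3
    preseq_sd: float = 20.0
    preseq_min: int = 7
    preseq_max: int = 117
    ratio_noise_sd: float = 0.2
    ratio_cap: float = 100.0
    leak: float = 0.02
    peptide_min_len: int = 7
    peptide_max_len: int = 45
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_mito", "fraction_no_presequence",
                     "fraction_icp55_substrate", "fraction_oct1_substrate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not np.isclose(sum(self.mpp_class_weights), 1.0):
            raise ConfigurationError("mpp_class_weights must sum to 1")
        if any(w < 0 for w in self.mpp_class_weights):
            raise ConfigurationError("mpp_class_weights must be non-negative")
        if self.ratio_cap < 1.0:
            raise ConfigurationError("ratio_cap must be >= 1")
        if self.preseq_min < 1 or self.preseq_max < self.preseq_min:
            raise ConfigurationError("invalid presequence length bounds")
        if self.preseq_sd <= 0:
            raise ConfigurationError("preseq_sd must be positive")
        if not 0.0 <= self.leak < 0.5:
            raise ConfigurationError("leak must be in [0, 0.5)")


@dataclass
class SimProtein:
    """A simulated protein with full processing ground truth."""

    accession: str
    sequence: str
    location_label: str  # mitochondrial / plastid / other
    mpp_site: int | None  # 1-based first residue after MPP cleavage
    mpp_class: str  # -3R / -2R / no-R / none
    icp55_removed: str  # residues removed by ICP55 after MPP ("" if none)
    oct1_removed_len: int  # residues removed by OCT1 (0 if none)
    met_removed: bool = False  # initiator Met excised (presequence-less only)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if self.mpp_site is not None:
            if not 2 <= self.mpp_site <= n:
                raise ValueError(f"{self.accession}: mpp_site out of bounds")
            if self.mpp_class == "-3R" and self.sequence[self.mpp_site - 4] != "R":
                raise ValueError(f"{self.accession}: -3R class without R at -3")
            if self.mpp_class == "-2R" and self.sequence[self.mpp_site - 3] != "R":
                raise ValueError(f"{self.accession}: -2R class without R at -2")
            if self.icp55_removed:
                k = len(self.icp55_removed)
                actual = self.sequence[self.mpp_site - 1: self.mpp_site - 1 + k]
                if actual != self.icp55_removed:
                    raise ValueError(
                        f"{self.accession}: icp55_removed {self.icp55_removed!r} "
                        f"does not match sequence {actual!r}"
                    )
        elif self.mpp_class != "none":
            raise ValueError(f"{self.accession}: mpp_class without mpp_site")
        if self.oct1_removed_len:
            start = self.mpp_site if self.mpp_site is not None else 2
            if start + self.oct1_removed_len > n:
                raise ValueError(f"{self.accession}: OCT1 segment out of bounds")

    @property
    def is_icp55_substrate(self) -> bool:
        return bool(self.icp55_removed)

    @property
    def is_oct1_substrate(self) -> bool:
        return self.oct1_removed_len > 0

    @property
    def precursor_start(self) -> int:
        return 2 if self.met_removed else 1

    @property
    def wt_mature_start(self) -> int:
        """Dominant N-terminal position in the wild type (fully processed)."""
        if self.mpp_site is not None:
            if self.icp55_removed:
                return self.mpp_site + len(self.icp55_removed)
            if self.oct1_removed_len:
                return self.mpp_site + self.oct1_removed_len
            return self.mpp_site
        if self.oct1_removed_len:  # MPP-independent OCT1 processing
            return 2 + self.oct1_removed_len
        return self.precursor_start

    def to_protein_record(self) -> ProteinRecord:
        return ProteinRecord(
            accession=self.accession,
            sequence=self.sequence,
            description="simulated",
            location_label=self.location_label,
        )


# ---------------------------------------------------------------------------
# Proteome generation
# ---------------------------------------------------------------------------

def _weights(freq: Mapping[str, float],
             exclude: str = "") -> tuple[list[str], np.ndarray]:
    items = [(aa, w) for aa, w in freq.items() if aa not in exclude]
    aas = [aa for aa, _ in items]
    w = np.array([v for _, v in items])
    return aas, w / w.sum()


def _draw(rng: np.random.Generator, freq: Mapping[str, float], n: int,
          exclude: str = "") -> str:
    aas, w = _weights(freq, exclude)
    return "".join(rng.choice(aas, size=n, p=w))


def _preseq_freq() -> dict[str, float]:
    f = dict(BACKGROUND_FREQ)
    for aa, mult in PRESEQ_ENRICHMENT.items():
        f[aa] *= mult
    total = sum(f.values())
    return {aa: v / total for aa, v in f.items()}


def _mature_body(rng: np.random.Generator, n_segments: int = 10) -> str:
    # ArgC-friendly body: stretches of 7-12 non-R residues punctuated by R,
    # so every terminus yields a peptide of tractable length.
    parts = []
    for _ in range(n_segments):
        k = int(rng.integers(7, 13))
        parts.append(_draw(rng, BACKGROUND_FREQ, k, exclude="R") + "R")
    return "".join(parts)


def _truncnorm_int(rng: np.random.Generator, mean: float, sd: float,
                   lo: int, hi: int) -> int:
    while True:
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return int(round(v))


def _make_presequence(rng: np.random.Generator, length: int,
                      mpp_class: str) -> str:
    freq = _preseq_freq()
    seq = list("M" + _draw(rng, freq, length - 1))
    # the MPP recognition arginine sits upstream of the cleavage site
    # (mpp_site = length + 1): -2 is index length-2, -3 is index length-3
    if mpp_class == "-3R":
        seq[length - 3] = "R"
    elif mpp_class == "-2R":
        seq[length - 2] = "R"
    else:  # no-R: make sure neither recognition position carries R
        for idx in (length - 2, length - 3):
            while seq[idx] == "R":
                seq[idx] = _draw(rng, freq, 1, exclude="R")
    return "".join(seq)


def generate_proteome(config: SimConfig) -> list[SimProtein]:
    """Simulate a proteome with processing ground truth, deterministically."""
    rng = np.random.default_rng(config.seed)
    proteins: list[SimProtein] = []
    for i in range(config.n_proteins):
        acc = f"SIM{i:05d}"
        mito = rng.random() < config.fraction_mito
        location = "mitochondrial" if mito else (
            "plastid" if rng.random() < 0.5 else "other"
        )
        has_preseq = mito and rng.random() >= config.fraction_no_presequence

        role = "none"
        if mito:
            u = rng.random()
            if has_preseq:
                if u < config.fraction_icp55_substrate:
                    role = "icp55"
                elif u < (config.fraction_icp55_substrate
                          + config.fraction_oct1_substrate):
                    role = "oct1"
            elif u < config.fraction_oct1_substrate:
                role = "oct1"  # MPP-independent, B13-style

        if role == "oct1" and not has_preseq:
            # MPP-independent OCT1 processing: short stretch removed from
            # position 2, no MPP site at all.
            removed_len = int(rng.integers(6, 20))
            first = rng.choice(ICP55_REMOVED_FIRST, p=ICP55_REMOVED_FIRST_W)
            segment = first + _draw(rng, BACKGROUND_FREQ, removed_len - 1,
                                    exclude="R")
            seq = "M" + segment + _mature_body(rng)
            proteins.append(SimProtein(
                accession=acc, sequence=seq, location_label=location,
                mpp_site=None, mpp_class="none", icp55_removed="",
                oct1_removed_len=removed_len,
            ))
            continue

        if not has_preseq:
            body = _mature_body(rng)
            seq = "M" + body
            met_removed = bool(seq[1] in "ASTGVCP" and rng.random() < 0.5)
            proteins.append(SimProtein(
                accession=acc, sequence=seq, location_label=location,
                mpp_site=None, mpp_class="none", icp55_removed="",
                oct1_removed_len=0, met_removed=met_removed,
            ))
            continue

        length = _truncnorm_int(
            rng, config.preseq_mean, config.preseq_sd,
            config.preseq_min, config.preseq_max,
        )
        mpp_class = MPP_CLASSES[
            rng.choice(3, p=np.asarray(config.mpp_class_weights))
        ]
        preseq = _make_presequence(rng, length, mpp_class)
        mpp_site = length + 1

        if role == "icp55":
            k = 2 if rng.random() < 0.1 else 1
            removed = str(rng.choice(ICP55_REMOVED_FIRST,
                                     p=ICP55_REMOVED_FIRST_W))
            if k == 2:
                removed += str(rng.choice(ICP55_REMOVED_SECOND))
            mature = (str(rng.choice(["S", "A"], p=[0.7, 0.3]))
                      + str(rng.choice(["S", "T"], p=[0.6, 0.4]))
                      + _draw(rng, BACKGROUND_FREQ, 5, exclude="R")
                      + _mature_body(rng))
            seq = preseq + removed + mature
            proteins.append(SimProtein(
                accession=acc, sequence=seq, location_label=location,
                mpp_site=mpp_site, mpp_class=mpp_class,
                icp55_removed=removed, oct1_removed_len=0,
            ))
        elif role == "oct1":
            removed_len = int(rng.integers(6, 20))
            first = rng.choice(ICP55_REMOVED_FIRST, p=ICP55_REMOVED_FIRST_W)
            segment = first + _draw(rng, BACKGROUND_FREQ, removed_len - 1,
                                    exclude="R")
            seq = preseq + segment + _mature_body(rng)
            proteins.append(SimProtein(
                accession=acc, sequence=seq, location_label=location,
                mpp_site=mpp_site, mpp_class=mpp_class, icp55_removed="",
                oct1_removed_len=removed_len,
            ))
        else:
            seq = preseq + _mature_body(rng)
            proteins.append(SimProtein(
                accession=acc, sequence=seq, location_label=location,
                mpp_site=mpp_site, mpp_class=mpp_class, icp55_removed="",
                oct1_removed_len=0,
            ))
    return proteins


# ---------------------------------------------------------------------------
# Processing cascades per genotype
# ---------------------------------------------------------------------------

def simulate_processing(
    protein: SimProtein, genotype: str, leak: float = 0.02
) -> list[tuple[int, float]]:
    """N-terminal species (1-based position, relative abundance) per genotype.

    The dominant species is the furthest-processed form the genotype can
    reach. Where a secondary peptidase acts downstream of MPP, the
    MPP-generated intermediate also leaks through at the ``leak`` fraction,
    emulating residual not-yet-trimmed material; in the corresponding
    knockout the intermediate is the only species. Abundances sum to 1.
    Proteins that are not substrates of the knocked-out peptidase give
    identical output for every genotype.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected {GENOTYPES}")

    if protein.mpp_site is None and not protein.oct1_removed_len:
        return [(protein.precursor_start, 1.0)]

    def species(dominant: int, minor: int) -> list[tuple[int, float]]:
        if leak == 0.0 or dominant == minor:
            return [(dominant, 1.0)]
        return [(dominant, 1.0 - leak), (minor, leak)]

    if protein.is_icp55_substrate:
        intermediate = protein.mpp_site
        final = protein.mpp_site + len(protein.icp55_removed)
        if genotype == "icp55":
            return [(intermediate, 1.0)]
        return species(final, intermediate)

    if protein.is_oct1_substrate:
        intermediate = protein.mpp_site if protein.mpp_site is not None else 2
        final = intermediate + protein.oct1_removed_len
        if genotype == "oct1":
            return [(intermediate, 1.0)]
        return species(final, intermediate)

    # MPP-only processing, identical in every genotype
    return [(protein.mpp_site, 1.0)]


# ---------------------------------------------------------------------------
# Observation model
# ---------------------------------------------------------------------------

def nterm_peptide(
    sequence: str, start: int, min_len: int = 7, max_len: int = 45
) -> str:
    """The N-terminal peptide generated from a terminus by ArgC-like digestion.

    The peptide runs from ``start`` to the first arginine giving a length of
    at least ``min_len`` (and at most ``max_len``); if no arginine qualifies
    the peptide is truncated at ``max_len`` or the protein end.
    """
    if not 1 <= start <= len(sequence):
        raise ValueError(f"terminus {start} beyond sequence end {len(sequence)}")
    idx = start - 1
    for j in range(idx, min(idx + max_len, len(sequence))):
        if sequence[j] == "R" and (j - idx + 1) >= min_len:
            return sequence[idx: j + 1]
    return sequence[idx: min(idx + max_len, len(sequence))]


def simulate_observations(
    wt_termini: Mapping[str, Sequence[tuple[int, float]]],
    mut_termini: Mapping[str, Sequence[tuple[int, float]]],
    proteins: Mapping[str, SimProtein],
    comparison_id: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[QuantifiedPeptide]:
    """Quantified N-terminal peptides for one mutant-vs-WT comparison.

    Each terminus present in either genotype yields one peptide; the
    reported ratio is (mutant abundance)/(WT abundance) with multiplicative
    log-normal noise on the log2 scale, clipped to [1/cap, cap]; termini
    absent from one channel are reported at the corresponding cap.
    """
    out: list[QuantifiedPeptide] = []
    for acc in sorted(set(wt_termini) | set(mut_termini)):
        protein = proteins[acc]
        wt = dict(wt_termini.get(acc, ()))
        mut = dict(mut_termini.get(acc, ()))
        for pos in sorted(set(wt) | set(mut)):
            wt_ab = wt.get(pos, 0.0)
            mut_ab = mut.get(pos, 0.0)
            if wt_ab == 0.0 and mut_ab == 0.0:
                continue
            if wt_ab == 0.0:
                ratio = config.ratio_cap
            elif mut_ab == 0.0:
                ratio = 1.0 / config.ratio_cap
            else:
                noise = rng.normal(0.0, config.ratio_noise_sd)
                ratio = (mut_ab / wt_ab) * 2.0 ** noise
            ratio = float(np.clip(ratio, 1.0 / config.ratio_cap,
                                  config.ratio_cap))
            pep = nterm_peptide(
                protein.sequence, pos,
                config.peptide_min_len, config.peptide_max_len,
            )
            out.append(QuantifiedPeptide(
                accession=acc,
                peptide=pep,
                nterm_mod="dimethyl",
                comparison_id=comparison_id,
                ratio_mut_over_wt=ratio,
                start=pos,
                end=pos + len(pep) - 1,
            ))
    out.sort(key=lambda p: (p.accession, p.start))
    return out


# ---------------------------------------------------------------------------
# Whole-experiment driver
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """A full simulated experiment with ground truth."""

    config: SimConfig
    proteins: list[SimProtein]
    peptides: dict[str, list[QuantifiedPeptide]]  # per comparison_id
    localization: dict[str, str]

    @property
    def protein_records(self) -> dict[str, ProteinRecord]:
        return {p.accession: p.to_protein_record() for p in self.proteins}

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {
                "accession": p.accession,
                "location": p.location_label,
                "mpp_site": p.mpp_site,
                "mpp_class": p.mpp_class,
                "icp55_removed": p.icp55_removed,
                "oct1_removed_len": p.oct1_removed_len,
                "wt_mature_start": p.wt_mature_start,
            }
            for p in self.proteins
        ]
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(
            [p.to_protein_record() for p in self.proteins],
            outdir / "proteome.fasta",
        )
        write_localization_table(self.localization, outdir / "localization.tsv")
        self.truth_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
        for comp, peps in self.peptides.items():
            write_peptide_table(peps, outdir / f"peptides_{comp}.tsv")
        with open(outdir / "seed.txt", "w") as fh:
            fh.write(f"{self.config.seed}\n")


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Simulate a proteome and all three knockout comparisons."""
    proteins = generate_proteome(config)
    by_acc = {p.accession: p for p in proteins}
    terms = {
        g: {p.accession: simulate_processing(p, g, config.leak)
            for p in proteins}
        for g in GENOTYPES
    }
    rng = np.random.default_rng(config.seed + 1)
    peptides = {
        "icp55": simulate_observations(
            terms["WT"], terms["icp55"], by_acc, "icp55", config, rng),
        "oct1_1": simulate_observations(
            terms["WT"], terms["oct1"], by_acc, "oct1_1", config, rng),
        "oct1_2": simulate_observations(
            terms["WT"], terms["oct1"], by_acc, "oct1_2", config, rng),
    }
    localization = {p.accession: p.location_label for p in proteins}
    return SimulatedDataset(
        config=config, proteins=proteins, peptides=peptides,
        localization=localization,
    )
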