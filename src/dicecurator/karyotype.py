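"""Reference human karyotype constants and ISCN group binning.

Chromosome areas in a segmented metaphase image are approximately
proportional to the DNA content of each chromosome, so the reference
genome's chromosome lengths provide a "gold standard" size distribution
against which an observed cell can be compared.  Chromosomes are collapsed
into three ISCN-derived size groups:

* ``AB`` -- groups A and B (chromosomes 1-5), each single chromosome
  holding more than 2.9% of the diploid genome;
* ``C``  -- group C plus X (chromosomes 6-12, X), between 2% and 2.9%;
* ``DG`` -- groups D through G plus Y (chromosomes 13-22, Y), below 2%.

The 2.9% and 2% cut points are the maximum relative lengths of the X and Y
chromosomes respectively.  An ideal female cell bins to (10, 16, 20) and an
ideal male cell to (10, 15, 21).
"""

from __future__ import annotations

import numpy as np

# GRCh38 primary-assembly sequence lengths (bp).
GRCH38_LENGTHS: dict[str, int] = {
    "1": 248956422, "2": 242193529, "3": 198295559, "4": 190214555,
    "5": 181538259, "6": 170805979, "7": 159345973, "8": 145138636,
    "9": 138394717, "10": 133797422, "11": 135086622, "12": 133275309,
    "13": 114364328, "14": 107043718, "15": 101991189, "16": 90338345,
    "17": 83257441, "18": 80373285, "19": 58617616, "20": 64444167,
    "21": 46709983, "22": 50818468, "X": 156040895, "Y": 57227415,
}

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))

#: Group thresholds as fractions of total diploid genome length.
AB_THRESHOLD = 0.029
DG_THRESHOLD = 0.02

#: Ideal (AB, C, DG) group counts.
IDEAL_COUNTS = {"female": (10, 16, 20), "male": (10, 15, 21)}


def diploid_complement(sex: str) -> list[str]:
    """Chromosome names of a normal diploid complement (46 entries)."""
    if sex not in ("female", "male"):
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    comp = [c for c in AUTOSOMES for _ in range(2)]
    comp += ["X", "X"] if sex == "female" else ["X", "Y"]
    return comp


def relative_lengths(sex: str) -> np.ndarray:
    """Per-chromosome fraction of the total diploid genome, one entry per
    chromosome of the complement (sums to 1)."""
    lengths = np.array([GRCH38_LENGTHS[c] for c in diploid_complement(sex)], float)
    return lengths / lengths.sum()


def classify_group(fraction: float,
                   thresholds: tuple[float, float] = (AB_THRESHOLD, DG_THRESHOLD)) -> str:
    """Bin a single chromosome's genome fraction into AB / C / DG.

    Boundary values are assigned by half-open intervals: exactly 2.9%
    falls in C, exactly 2% falls in DG.
    """
    if fraction > thresholds[0]:
        return "AB"
    if fraction > thresholds[1]:
        return "C"
    return "DG"


def group_counts(fractions,
                 thresholds: tuple[float, float] = (AB_THRESHOLD, DG_THRESHOLD)
                 ) -> tuple[int, int, int]:
    """Count (AB, C, DG) chromosomes from relative areas/lengths."""
    ab = c = dg = 0
    for f in np.asarray(fractions, float):
        g = classify_group(f, thresholds)
        if g == "AB":
            ab += 1
        elif g == "C":
            c += 1
        else:
            dg += 1
    return ab, c, dg


def ideal_group_counts(sex: str) -> tuple[int, int, int]:
    """Ideal (AB, C, DG) vector computed from the bundled reference lengths."""
    return group_counts(relative_lengths(sex))
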