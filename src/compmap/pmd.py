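"""Post-mortem damage likelihood scores and per-sample summaries.

Ancient DNA carries an excess of C->T substitutions near the 5' end of the
molecule and G->A near the 3' end, caused by cytosine deamination in
single-stranded overhangs. The per-read score is a natural-log likelihood
ratio comparing a position-dependent damage model against a null model;
the per-sample ratio (fraction of reads scoring above a threshold) and the
median read length are the two authentication summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

from ._fasta import revcomp
from .classify import AlignedRead

PMD_SCORE_THRESHOLD = 5.0


@dataclass(frozen=True)
class DamageModel:
    """Geometric-decay damage model.

    D(z) = p * (1 - p)^(z - 1) + c for 1-based distance z from the relevant
    fragment end; ``pi`` is the background polymorphism probability used by
    the null model.
    """

    p: float = 0.3
    c: float = 0.01
    pi: float = 0.001

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if not (0.0 <= self.c < 1.0):
            raise ValueError(f"c must be in [0, 1), got {self.c}")
        if not (0.0 <= self.pi < 1.0):
            raise ValueError(f"pi must be in [0, 1), got {self.pi}")


def damage_probability(z: int, model: DamageModel) -> float:
    """D(z) = p*(1-p)^(z-1) + c, clamped to [0, 1]; z is 1-based."""
    if z < 1:
        raise ValueError(f"z must be >= 1, got {z}")
    d = model.p * (1.0 - model.p) ** (z - 1) + model.c
    return min(1.0, max(0.0, d))


@dataclass
class PmdResult:
    query_name: str
    score: float
    n_informative_sites: int


def _site_log_ratio(obs: str, damaged_base: str, undamaged_base: str,
                    m: float, pi: float, eps: float) -> Optional[float]:
    """ln(L_damage / L_null) for one informative site, or None when the
    observed base is neither the damaged nor the undamaged state."""
    m_null = pi
    if obs == damaged_base:
        l_d = m * (1.0 - eps) + (1.0 - m) * eps / 3.0
        l_n = m_null * (1.0 - eps) + (1.0 - m_null) * eps / 3.0
    elif obs == undamaged_base:
        l_d = (1.0 - m) * (1.0 - eps) + m * eps / 3.0
        l_n = (1.0 - m_null) * (1.0 - eps) + m_null * eps / 3.0
    else:
        return None
    return math.log(l_d) - math.log(l_n)


def pmd_score(read: AlignedRead, model: DamageModel = DamageModel()) -> PmdResult:
    """Natural-log likelihood-ratio damage score for one mapped read.

    Informative sites are aligned positions whose reference base is C
    (distance z measured from the molecule's 5' end) or G (z from the 3'
    end). Scoring happens in original-molecule orientation: minus-strand
    alignments are reverse-complemented first. With damage probability
    D(z), polymorphism pi and sequencing error eps = 10^(-Q/10), the
    effective mismatch probability is m(z) = D(z) + pi - D(z)*pi; the null
    model uses m = pi. Query positions without an aligned reference base
    (indels, clips) are skipped.
    """
    if read.is_unmapped:
        raise ValueError(f"{read.query_name}: cannot score an unmapped read")
    if read.ref_bases is None:
        raise ValueError(
            f"{read.query_name}: aligned reference bases unavailable; supply "
            "a reference FASTA or alignments with MD tags"
        )
    bases = read.bases.upper()
    ref = read.ref_bases.upper()
    quals = list(read.qualities)
    if read.strand == "-":
        bases = revcomp(bases)
        ref = ref.translate(str.maketrans("ACGTN-", "TGCAN-"))[::-1]
        quals = quals[::-1]

    L = len(bases)
    score = 0.0
    n_sites = 0
    for i in range(L):
        r = ref[i]
        if r == "C":
            z = i + 1
            pair = ("T", "C")
        elif r == "G":
            z = L - i
            pair = ("A", "G")
        else:
            continue
        d = damage_probability(z, model)
        m = d + model.pi - d * model.pi
        eps = 10.0 ** (-quals[i] / 10.0)
        contrib = _site_log_ratio(bases[i], pair[0], pair[1], m, model.pi, eps)
        if contrib is None:
            continue
        score += contrib
        n_sites += 1
    if n_sites == 0:
        score = 0.0
    return PmdResult(read.query_name, score, n_sites)


def pmd_ratio(
    results: Iterable[PmdResult], threshold: float = PMD_SCORE_THRESHOLD
) -> Optional[float]:
    """Fraction of reads with score strictly above ``threshold``."""
    scores = [r.score for r in results]
    if not scores:
        warnings.warn("no PMD results: ratio undefined")
        return None
    return sum(1 for s in scores if s > threshold) / len(scores)


def median_read_length(reads: Iterable[AlignedRead]) -> Optional[float]:
    """Median alignment length; mean of the two central values for even n."""
    lengths = sorted(r.alignment_length for r in reads)
    if not lengths:
        warnings.warn("no reads: median read length undefined")
        return None
    n = len(lengths)
    mid = n // 2
    if n % 2:
        return float(lengths[mid])
    return (lengths[mid - 1] + lengths[mid]) / 2.0


def write_pmd_tsv(results: Sequence[PmdResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("query_name\tscore\tn_informative_sites\n")
        for r in results:
            fh.write(f"{r.query_name}\t{r.score:.6f}\t{r.n_informative_sites}\n")


def load_pmd_tsv(path) -> List[PmdResult]:
    out: List[PmdResult] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["query_name", "score", "n_informative_sites"]:
            raise ValueError(f"unexpected PMD TSV header in {path}: {header}")
        for line in fh:
            name, score, n = line.rstrip("\n").split("\t")
            out.append(PmdResult(name, float(score), int(n)))
    return out
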