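"""In-silico proteolytic digestion of sequence forms.

Fully-specific digestion with missed cleavages. Two trypsin dialects are
provided because search engines disagree: classical ``trypsin`` cleaves
C-terminal to K/R except before proline; ``trypsin_p`` cleaves after K/R
unconditionally. ``none`` performs no cleavage (the whole form is one
peptide). The dialect used to build a unicity table must match the
upstream search engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .proteome import ConfigError, SequenceForm

ENZYMES = ("trypsin", "trypsin_p", "none")


@dataclass(frozen=True)
class DigestSpec:
    """Digestion parameters.

    Defaults: classical trypsin, up to 2 missed cleavages, peptide length
    7..45 (shorter peptides are rarely informative for unicity).
    """

    enzyme: str = "trypsin"
    max_missed: int = 2
    min_len: int = 7
    max_len: int = 45

    def __post_init__(self) -> None:
        if self.enzyme not in ENZYMES:
            raise ConfigError(f"unknown enzyme {self.enzyme!r}; one of {ENZYMES}")
        if self.max_missed < 0:
            raise ConfigError("max_missed must be >= 0")
        if not (1 <= self.min_len <= self.max_len):
            raise ConfigError("need 1 <= min_len <= max_len")

    def describe(self) -> str:
        return (
            f"enzyme={self.enzyme} max_missed={self.max_missed} "
            f"min_len={self.min_len} max_len={self.max_len}"
        )


@dataclass(frozen=True)
class TheoreticalPeptide:
    sequence: str
    form_ref: SequenceForm
    start: int  # 1-based inclusive within the form
    end: int
    missed: int
    carries_variant: bool = False


def cleavage_sites(seq: str, enzyme: str) -> list[int]:
    """0-based indices i such that the enzyme cuts between seq[i] and seq[i+1]."""
    if enzyme == "none":
        return []
    sites = []
    for i in range(len(seq) - 1):
        if seq[i] in "KR":
            if enzyme == "trypsin" and seq[i + 1] == "P":
                continue
            sites.append(i)
    return sites


def digest(form: SequenceForm, spec: DigestSpec = DigestSpec()) -> list[TheoreticalPeptide]:
    """Fully-specific peptides of a form with 0..max_missed missed cleavages.

    The length filter applies last; output is ordered by (start, end).
    """
    seq = form.seq
    if not seq:
        return []
    sites = cleavage_sites(seq, spec.enzyme)
    # segment boundaries: fragment f spans bounds[f]..bounds[f+1]-1 (0-based)
    bounds = [0] + [i + 1 for i in sites] + [len(seq)]
    n_frag = len(bounds) - 1
    peptides = []
    for f in range(n_frag):
        for missed in range(min(spec.max_missed, n_frag - 1 - f) + 1):
            start0, end0 = bounds[f], bounds[f + 1 + missed] - 1
            length = end0 - start0 + 1
            if not (spec.min_len <= length <= spec.max_len):
                continue
            start, end = start0 + 1, end0 + 1
            carries = bool(
                form.carries_variant
                and form.variant_pos is not None
                and start <= form.variant_pos <= end
            )
            peptides.append(
                TheoreticalPeptide(
                    sequence=seq[start0 : end0 + 1],
                    form_ref=form,
                    start=start,
                    end=end,
                    missed=missed,
                    carries_variant=carries,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def digest_proteome(
    forms: Iterable[SequenceForm], spec: DigestSpec = DigestSpec()
) -> Iterator[TheoreticalPeptide]:
    """Concatenated per-form digests, form order preserved."""
    for form in forms:
        yield from digest(form, spec)
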