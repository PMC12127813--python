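"""Transcript-consequence arithmetic for aberrant splice events.

Minigene assays read out two classes of aberrant transcript: skipping of a
whole exon (the transcript loses that exon's length) and retention of
intronic sequence (the transcript gains the retained length). The coding
consequence follows from length arithmetic alone: a net change that is a
multiple of three preserves the reading frame (an in-frame deletion when
negative), anything else shifts the frame. No stop-codon scanning is
performed; frameshift outputs report "fs" without a computed termination
position.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TranscriptModel", "SpliceEvent", "Consequence", "apply_event"]


@dataclass(frozen=True)
class TranscriptModel:
    """Exon-chain model of a transcript.

    ``exon_lengths`` are the spliced exon lengths in bp, 5' to 3'.
    ``cds_start_exon`` / ``cds_start_offset`` locate the translation start
    (0-based exon index, 0-based offset within that exon); exons are fully
    coding downstream of the start.
    """

    exon_lengths: tuple[int, ...]
    cds_start_exon: int = 0
    cds_start_offset: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "exon_lengths", tuple(int(x) for x in self.exon_lengths))
        if not self.exon_lengths:
            raise ValueError("transcript needs at least one exon")
        if any(x <= 0 for x in self.exon_lengths):
            raise ValueError("exon lengths must be positive")
        if not 0 <= self.cds_start_exon < len(self.exon_lengths):
            raise ValueError("cds_start_exon outside the exon chain")
        if not 0 <= self.cds_start_offset < self.exon_lengths[self.cds_start_exon]:
            raise ValueError("cds_start_offset outside its exon")

    @property
    def n_exons(self) -> int:
        return len(self.exon_lengths)


@dataclass(frozen=True)
class SpliceEvent:
    """An exon skip or an intron retention.

    For ``exon_skip``, ``exon_index`` is the 1-based index of the skipped
    exon. For ``intron_retention``, it is the 1-based index of the exon
    after which the intron is retained, and ``retained_length`` the number
    of intronic bp incorporated into the transcript.
    """

    kind: str
    exon_index: int
    retained_length: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("exon_skip", "intron_retention"):
            raise ValueError(f"unknown splice event kind: {self.kind!r}")
        if self.exon_index < 1:
            raise ValueError("exon_index is 1-based and must be >= 1")
        if self.kind == "intron_retention":
            if self.retained_length is None or self.retained_length <= 0:
                raise ValueError("intron_retention requires retained_length > 0")
        elif self.retained_length is not None:
            raise ValueError("retained_length only applies to intron_retention")


@dataclass(frozen=True)
class Consequence:
    """Coding consequence of a splice event: the bp change and its frame effect."""

    kind: str  # in_frame_deletion | frameshift | identity | in_frame_insertion
    delta_bp: int
    aa_removed: int = 0

    @property
    def hgvs_suffix(self) -> str:
        """Short HGVS-style tag: 'fs' for frameshifts, 'del<N>aa' for in-frame losses."""
        if self.kind == "frameshift":
            return "fs"
        if self.kind == "in_frame_deletion":
            return f"del{self.aa_removed}aa"
        if self.kind == "in_frame_insertion":
            return f"ins{self.delta_bp // 3}aa"
        return "="


def apply_event(t: TranscriptModel, e: SpliceEvent) -> Consequence:
    """Compute the coding consequence of one splice event on a transcript.

    The bp change is minus the exon length for a skip and plus the retained
    length for an intron retention; the consequence class follows from
    mod-3 arithmetic on that change.
    """
    if e.exon_index > t.n_exons:
        raise ValueError(
            f"event exon index {e.exon_index} outside transcript with {t.n_exons} exons"
        )
    if e.kind == "exon_skip":
        if e.exon_index - 1 < t.cds_start_exon:
            raise ValueError("skipped exon lies entirely in the 5' UTR")
        delta = -t.exon_lengths[e.exon_index - 1]
        if e.exon_index - 1 == t.cds_start_exon:
            delta += t.cds_start_offset  # UTR portion of the start exon is non-coding
    else:
        if e.exon_index == t.n_exons:
            raise ValueError("no intron downstream of the last exon")
        delta = int(e.retained_length)  # type: ignore[arg-type]

    if delta == 0:
        return Consequence("identity", 0)
    if delta % 3 != 0:
        return Consequence("frameshift", delta)
    if delta < 0:
        return Consequence("in_frame_deletion", delta, aa_removed=-delta // 3)
    return Consequence("in_frame_insertion", delta)
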