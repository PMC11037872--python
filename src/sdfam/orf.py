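"""ORF frameshift and C-terminal extension analysis.

Given a transcript and the ancestral reference CDS, the analyzer aligns the
full CDS within the transcript (infix alignment, so UTRs cost nothing),
infers the net coding indel from the cigar, and reports whether the reading
frame shifted, how many reference residues were lost before the ancestral
stop, and how many novel residues are translated past the ancestral stop
position until the first in-frame stop — the signature of an indel-driven
C-terminal extension.

Frame logic comes from the alignment; residue counts come from translating
the transcript's actual reading frame, so a 43 bp deletion is reported as a
frameshift with a novel extension while a 42 bp deletion is an in-frame
loss of 14 residues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align
from Bio.Seq import Seq

from .simulate import _common_prefix


def _aligner() -> Align.PairwiseAligner:
    """Affine-gap aligner fitting the full CDS inside the transcript.

    Transcript end overhangs (UTRs) are free; internal gaps are affine with
    a near-zero extension cost and a stiff mismatch penalty, so a
    contiguous indel is never traded for runs of chance mismatches — even
    when the only anchor beyond a deletion is the stop codon itself.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -6
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -0.1
    aligner.open_end_deletion_score = 0
    aligner.extend_end_deletion_score = 0
    return aligner


@dataclass
class OrfReport:
    orf_start: int               # on the transcript
    orf_end: int                 # end of translated region incl. stop
    anchored_to_canonical: bool
    frameshift: bool
    residues_removed: int
    extension_length_aa: int
    net_indel_bp: int


def _translate_frame(seq: str) -> str:
    trimmed = seq[: len(seq) - len(seq) % 3]
    return str(Seq(trimmed).translate(to_stop=True))


def orf_frameshift_report(
    transcript: str,
    reference_cds: str,
    anchor_slop_bp: int = 100,
    canonical_start: int | None = None,
) -> OrfReport:
    """Compare a transcript's ORF against the reference CDS.

    ``reference_cds`` must be a complete in-frame CDS (ATG ... stop); the
    transcript may extend past it on either side (UTRs). When
    ``canonical_start`` (expected ORF start on the transcript) is given,
    anchoring checks that the inferred start lies within ``anchor_slop_bp``
    of it; otherwise anchoring requires an ATG at the inferred start and an
    in-frame stop within the transcript.
    """
    if len(reference_cds) % 3 != 0:
        raise ValueError("reference CDS length not divisible by 3")
    stop_start = len(reference_cds) - 3
    alignment = _aligner().align(transcript, reference_cds)[0]
    t_blocks, r_blocks = alignment.aligned
    orf_start = int(t_blocks[0][0]) - int(r_blocks[0][0])

    # net indel (transcript minus reference) over the coding region before
    # the ancestral stop
    net_indel = 0
    prev_t = prev_r = None
    for (ts, te), (rs, re) in zip(t_blocks, r_blocks):
        if prev_t is not None:
            ins = int(ts) - prev_t          # transcript-only bases
            dele = int(rs) - prev_r         # reference-only bases
            if prev_r < stop_start:
                net_indel += ins
                net_indel -= min(dele, stop_start - prev_r)
        prev_t, prev_r = int(te), int(re)
    frameshift = (net_indel % 3) != 0

    # translate the transcript's own reading frame from the inferred start
    p_ref = str(Seq(reference_cds[:stop_start]).translate())
    coding = transcript[orf_start:]
    p_mut = _translate_frame(coding)

    pre = _common_prefix(p_ref, p_mut)
    if frameshift:
        removed = len(p_ref) - pre
    else:
        rest_ref, rest_mut = p_ref[pre:], p_mut[pre:]
        suf = _common_prefix(rest_ref[::-1], rest_mut[::-1])
        suf = min(suf, len(rest_mut))
        removed = len(p_ref) - pre - suf

    # ancestral stop position in transcript reading-frame coordinates
    s_prime = stop_start + net_indel
    extension = max(0, len(p_mut) - math.ceil(s_prime / 3))

    has_stop = 3 * len(p_mut) + 3 <= len(coding)
    if canonical_start is not None:
        anchored = abs(orf_start - canonical_start) <= anchor_slop_bp
    else:
        anchored = coding.startswith("ATG") and has_stop
    return OrfReport(
        orf_start=orf_start,
        orf_end=orf_start + 3 * len(p_mut) + (3 if has_stop else 0),
        anchored_to_canonical=bool(anchored),
        frameshift=bool(frameshift),
        residues_removed=int(removed),
        extension_length_aa=int(extension),
        net_indel_bp=int(net_indel),
    )
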