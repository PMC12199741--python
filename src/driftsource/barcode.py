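"""DNA-barcode identity ranking and the multi-marker confirmation rule.

Candidate sequences (e.g., herbarium amplicons) are scored against a reference
organism by percent identity and ranked.  Identity is computed over aligned
columns where both rows carry a base, after stripping terminal-gap columns:
internal indels penalise, ragged amplicon ends do not.  A candidate is
*confirmed* only when all three of the rbcL, COI and SSU barcodes exceed 99%
identity AND the site has an eDNA detection; the same identities without a
detection are *provisional*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .errors import ValidationError
from .landings import round_half_up

MARKERS = ("UPA", "rbcL", "COI", "SSU")
GAP = "-"


@dataclass
class SequenceRecord:
    """A barcode sequence, optionally gapped if pre-aligned."""

    id: str
    seq: str
    marker: str = "UPA"
    taxon: str = ""

    def __post_init__(self):
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValidationError(f"sequence {self.id}: empty")
        bad = set(self.seq) - set("ACGTRYSWKMBDHVN" + GAP)
        if bad:
            raise ValidationError(f"sequence {self.id}: invalid characters {sorted(bad)}")


def read_fasta(path, marker: str = "UPA") -> List[SequenceRecord]:
    return [SequenceRecord(id=r.id, seq=str(r.seq), marker=marker,
                           taxon=r.description.partition(" ")[2])
            for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Sequence[SequenceRecord], path):
    SeqIO.write([BioSeqRecord(Seq(r.seq), id=r.id, description=r.taxon)
                 for r in records], str(path), "fasta")


def align_pair(a: SequenceRecord, b: SequenceRecord,
               match: float = 1.0, mismatch: float = -1.0,
               gap: float = -2.0) -> Tuple[SequenceRecord, SequenceRecord, float]:
    """Optimal global (Needleman–Wunsch) alignment under linear gap scores.

    Ties in the traceback are broken deterministically: diagonal, then up
    (gap in ``b``), then left.  Returns the two gapped records and the score.
    """
    if a.marker != b.marker:
        raise ValidationError("sequences have different markers")
    s1 = a.seq.upper().replace(GAP, "")
    s2 = b.seq.upper().replace(GAP, "")
    if not s1 or not s2:
        raise ValidationError("cannot align an empty sequence")
    n, m = len(s1), len(s2)
    score = np.empty((n + 1, m + 1))
    score[0, :] = gap * np.arange(m + 1)
    score[:, 0] = gap * np.arange(n + 1)
    x = np.frombuffer(s1.encode(), dtype=np.uint8)
    y = np.frombuffer(s2.encode(), dtype=np.uint8)
    sub = np.where(x[:, None] == y[None, :], match, mismatch)
    for i in range(1, n + 1):
        row_prev = score[i - 1]
        row = score[i]
        diag = row_prev[:-1] + sub[i - 1]
        up = row_prev[1:] + gap
        best = np.maximum(diag, up)
        acc = score[i, 0]
        for j in range(1, m + 1):  # left moves are serial in j
            acc = max(best[j - 1], acc + gap)
            row[j] = acc

    # traceback with the documented tie order
    ai, bi = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and np.isclose(score[i, j], score[i - 1, j - 1] + sub[i - 1, j - 1]):
            ai.append(s1[i - 1]); bi.append(s2[j - 1]); i -= 1; j -= 1
        elif i > 0 and np.isclose(score[i, j], score[i - 1, j] + gap):
            ai.append(s1[i - 1]); bi.append(GAP); i -= 1
        else:
            ai.append(GAP); bi.append(s2[j - 1]); j -= 1
    ga = SequenceRecord(id=a.id, seq="".join(reversed(ai)), marker=a.marker, taxon=a.taxon)
    gb = SequenceRecord(id=b.id, seq="".join(reversed(bi)), marker=b.marker, taxon=b.taxon)
    return ga, gb, float(score[n, m])


def percent_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """100 × matches / comparable columns, terminal-gap columns stripped.

    Comparable columns are those where both rows carry a base (no internal
    gap).  Raises on unequal aligned lengths.
    """
    sa, sb = a.seq.upper(), b.seq.upper()
    if len(sa) != len(sb):
        raise ValidationError("aligned sequences differ in length")
    arr_a = np.array(list(sa))
    arr_b = np.array(list(sb))
    nongap = (arr_a != GAP) & (arr_b != GAP)
    both = np.flatnonzero((arr_a != GAP)) , np.flatnonzero((arr_b != GAP))
    # strip terminal-gap columns: keep the window where both rows have started
    # and neither has ended
    start = max(both[0][0], both[1][0])
    end = min(both[0][-1], both[1][-1])
    window = np.zeros(len(sa), dtype=bool)
    window[start:end + 1] = True
    comparable = nongap & window
    if not comparable.any():
        raise ValidationError("no comparable columns")
    matches = np.sum(arr_a[comparable] == arr_b[comparable])
    return 100.0 * float(matches) / float(comparable.sum())


def rank_against_reference(candidates: Sequence[SequenceRecord],
                           reference: SequenceRecord,
                           aligned: bool = False) -> pd.DataFrame:
    """Percent identity of every candidate vs the reference, sorted descending.

    ``aligned=True`` treats inputs as rows of one multiple alignment (equal
    lengths); otherwise each candidate is globally aligned to the reference
    first.  Ties are ordered by candidate id.  The report carries both the
    exact identity and its one-decimal display value.
    """
    rows = []
    for cand in candidates:
        if cand.marker != reference.marker:
            raise ValidationError(f"candidate {cand.id}: marker mismatch")
        if aligned:
            ga, gb = cand, reference
        else:
            ga, gb, _ = align_pair(cand, reference)
        nongap_a = np.array(list(ga.seq)) != GAP
        nongap_b = np.array(list(gb.seq)) != GAP
        rows.append({"candidate_id": cand.id, "taxon": cand.taxon,
                     "identity": percent_identity(ga, gb),
                     "columns": int(np.sum(nongap_a & nongap_b))})
    df = pd.DataFrame(rows, columns=["candidate_id", "taxon", "identity", "columns"])
    if not df.empty:
        df["identity_1dp"] = df["identity"].map(lambda p: round_half_up(p, 1))
        df = df.sort_values(["identity", "candidate_id"],
                            ascending=[False, True], kind="stable").reset_index(drop=True)
    df.attrs["reference_id"] = reference.id
    return df


def confirm_candidate(identities: Dict[str, float], edna_detected: bool) -> str:
    """Multi-marker confirmation rule.

    confirmed: rbcL, COI and SSU all > 99% identity AND an eDNA detection;
    provisional: all three > 99% without a detection; rejected otherwise.
    """
    required = ("rbcL", "COI", "SSU")
    missing = [m for m in required if m not in identities]
    if missing:
        raise ValidationError(f"missing marker identities: {missing}")
    all_high = all(identities[m] > 99.0 for m in required)
    if all_high and edna_detected:
        return "confirmed"
    if all_high:
        return "provisional"
    return "rejected"
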