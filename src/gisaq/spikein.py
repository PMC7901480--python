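"""Detection of internal-standard reads/features and spike-in partitioning.

Spike-in reads are recognised either by a standard's specific primer pair
(both sites present, correctly oriented, with plausible spacing) or, when no
pair is attached, by alignment-free containment of the read in the standard's
amplicon region. Matching is Hamming-distance bounded (no indels): primer
sites in amplicon reads are rarely indel-bearing and this keeps detection
O(reads x standards). Reads matching two or more standards are ambiguous and
excluded from both — never double-counted.

Feature-table partitioning removes mapped spike-in features from the
community table while conserving per-sample totals exactly; raw counts are
used throughout (no rarefaction or normalisation happens here).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd

from .errors import GisaqError, InvalidSequenceError
from .standards import InternalStandard, normalize_sequence, reverse_complement


@dataclass
class DetectionResult:
    """Per-standard read counts for one sample plus the unassigned remainder."""

    sample: str
    region: str
    counts: dict[str, int]
    residual_ids: list[str]
    ambiguous_ids: list[str]

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + len(self.residual_ids) + len(self.ambiguous_ids)


def hamming_find(haystack: str, needle: str, max_mismatches: int) -> int:
    """First position where ``needle`` occurs in ``haystack`` within a Hamming
    bound, or -1. Naive scan with early abandon."""
    n, m = len(haystack), len(needle)
    for i in range(n - m + 1):
        mm = 0
        for a, b in zip(needle, haystack[i : i + m]):
            if a != b:
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            return i
    return -1


def _recognizers(standards: Sequence[InternalStandard], region: str) -> dict[str, tuple]:
    recs: dict[str, tuple] = {}
    for st in standards:
        if st.specific_primers is not None:
            fwd = st.specific_primers.forward
            rev_site = reverse_complement(st.specific_primers.reverse)
            recs[st.id] = ("pair", fwd, rev_site)
        else:
            recs[st.id] = ("amplicon", st.amplicon(region))
    seen: dict[tuple, str] = {}
    for sid, rec in recs.items():
        if rec in seen:
            raise GisaqError(
                f"standards {seen[rec]} and {sid} share an identical recognition "
                "sequence; detection would be ambiguous by construction"
            )
        seen[rec] = sid
    return recs


def _matches(seq: str, rec: tuple, max_mismatches: int) -> bool:
    for template in (seq, reverse_complement(seq)):
        if rec[0] == "pair":
            _, fwd, rev_site = rec
            pf = hamming_find(template, fwd, max_mismatches)
            if pf >= 0:
                tail = template[pf + len(fwd):]
                if hamming_find(tail, rev_site, max_mismatches) >= 0:
                    return True
        else:
            _, amplicon = rec
            short, long_ = sorted((template, amplicon), key=len)
            if hamming_find(long_, short, max_mismatches) >= 0:
                return True
    return False


def detect_standard_reads(reads: Iterable, standards: Sequence[InternalStandard],
                          max_mismatches: int = 2, region: str = "16S_V3V4",
                          sample: str = "sample") -> DetectionResult:
    """Assign reads to internal standards; unassigned reads form the residual.

    ``reads`` are Bio.SeqRecord objects or (id, sequence) pairs. A read is
    assigned to a standard iff its recognition sequence occurs (either
    strand) within the Hamming bound; reads matching several standards are
    counted as ambiguous. Counts + residual + ambiguous = input size.
    """
    recs = _recognizers(standards, region)
    counts = {st.id: 0 for st in standards}
    residual: list[str] = []
    ambiguous: list[str] = []
    for read in reads:
        if isinstance(read, tuple):
            rid, seq = read
        else:
            rid, seq = read.id, str(read.seq)
        seq = normalize_sequence(seq)
        hits = [sid for sid, rec in recs.items() if _matches(seq, rec, max_mismatches)]
        if len(hits) == 1:
            counts[hits[0]] += 1
        elif len(hits) > 1:
            ambiguous.append(rid)
        else:
            residual.append(rid)
    return DetectionResult(sample=sample, region=region, counts=counts,
                           residual_ids=residual, ambiguous_ids=ambiguous)


def assign_standard_features(representative_seqs: Mapping[str, str],
                             standards: Sequence[InternalStandard],
                             min_identity: float = 0.97,
                             region: str = "16S_V3V4") -> dict[str, str]:
    """Map feature ids to standard ids by global sequence identity.

    Identity is 1 - edit_distance / max(lengths) under global (NW) alignment.
    A feature maps to at most one standard (the best-identity hit).
    """
    if not 0.9 < min_identity <= 1.0:
        raise ValueError("min_identity must be in (0.9, 1]")
    mapping: dict[str, str] = {}
    for fid, rep in representative_seqs.items():
        if not rep:
            raise InvalidSequenceError(f"feature {fid!r} has no representative sequence")
        rep = normalize_sequence(rep)
        best_id, best_ident = None, 0.0
        for st in standards:
            amp = st.amplicon(region)
            d = edlib.align(rep, amp, mode="NW")["editDistance"]
            ident = 1.0 - d / max(len(rep), len(amp))
            if ident > best_ident:
                best_id, best_ident = st.id, ident
        if best_id is not None and best_ident >= min_identity:
            mapping[fid] = best_id
    return mapping


def partition_feature_table(table: pd.DataFrame,
                            standard_feature_map: Mapping[str, str],
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a features-x-samples count table into spike-in and community parts.

    Returns ``(standard_counts, community_table)`` where ``standard_counts``
    is standards x samples (features mapping to the same standard are summed)
    and per-sample totals are conserved exactly.
    """
    unknown = set(standard_feature_map) - set(table.index)
    if unknown:
        raise KeyError(f"standard features not in table: {sorted(unknown)}")
    std_features = list(standard_feature_map)
    community = table.drop(index=std_features)
    if std_features:
        std_part = table.loc[std_features].copy()
        std_part.index = [standard_feature_map[f] for f in std_features]
        standard_counts = std_part.groupby(level=0).sum()
    else:
        standard_counts = table.iloc[0:0].copy()
    return standard_counts, community
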