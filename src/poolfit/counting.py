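"""From barcode FASTQ to a CountTable.

Each read is a fixed-layout amplicon: a 5-nt multiplex tag identifying the
sample (pool, condition, replicate, time point), a common primer segment, the
20-nt strain barcode, and a trailing primer segment.  Counting proceeds as:

1. demultiplex — exact (zero-mismatch) match of the 5-nt prefix to the
   sample manifest; non-matching reads are tallied as *unassigned*;
2. primer trim — the expected 5' primer must match exactly at its offset
   (which also identifies the barcode position, B1 vs B2); otherwise the read
   is discarded into the *unmatched* tally;
3. barcode match — the strain barcode is matched against the reference
   allowing at most one substitution (Hamming distance); reads matching two
   or more reference tags are tallied *ambiguous*, reads matching none
   *unmatched*.

The per-sample accounting identity ``assigned + unassigned + ambiguous +
unmatched == total`` is asserted after every run.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .config import ConfigurationError
from .simulate import BARCODE_POSITIONS, COUNT_COLUMNS, MANIFEST_COLUMNS, PRIMERS

AMBIGUOUS = "__ambiguous__"


class Hamming1Matcher:
    """Exact or one-mismatch barcode lookup via a precomputed neighbourhood.

    Every reference tag indexes itself and its 3*L single-substitution
    neighbours.  A query hitting a key claimed by two different tags is
    ambiguous.  Lookup is O(1) per read.
    """

    def __init__(self, tags: Iterable[tuple[str, str]], max_mismatch: int = 1):
        if max_mismatch not in (0, 1):
            raise ConfigurationError("max_mismatch must be 0 or 1")
        self.max_mismatch = max_mismatch
        self._exact: dict[str, str] = {}
        self._near: dict[str, str] = {}
        self.tag_length: int | None = None
        tags = list(tags)
        for seq, strain in tags:
            if self.tag_length is None:
                self.tag_length = len(seq)
            elif len(seq) != self.tag_length:
                raise ConfigurationError(
                    f"reference tags have mixed lengths ({self.tag_length} vs {len(seq)})"
                )
            if seq in self._exact:
                self._exact[seq] = AMBIGUOUS
            else:
                self._exact[seq] = strain
        if max_mismatch == 1:
            for seq, strain in tags:
                for i, orig in enumerate(seq):
                    for b in "ACGT":
                        if b == orig:
                            continue
                        neigh = seq[:i] + b + seq[i + 1 :]
                        owner = self._near.get(neigh)
                        if owner is None:
                            self._near[neigh] = strain
                        elif owner != strain:
                            self._near[neigh] = AMBIGUOUS

    def match(self, candidate: str) -> str | None:
        """Strain id for a barcode candidate; AMBIGUOUS or None when unresolved.

        A candidate within distance <= 1 of two or more reference tags is
        ambiguous even if one of the matches is exact (conservative: such a
        reference is itself pathological, tags should be >= 3 apart).
        """
        if len(candidate) != self.tag_length:
            return None
        exact = self._exact.get(candidate)
        near = self._near.get(candidate) if self.max_mismatch else None
        if exact is not None and near is not None and near != exact:
            return AMBIGUOUS
        if exact is not None:
            return exact
        return near


def match_barcode(candidate: str, tags: Iterable[tuple[str, str]], max_mismatch: int = 1) -> str | None:
    """One-shot strain lookup for a barcode candidate.

    ``tags`` are (sequence, strain_id) pairs.  Returns the unique strain
    within ``max_mismatch`` substitutions, ``AMBIGUOUS`` when two or more
    qualify, or None.  For repeated lookups build a :class:`Hamming1Matcher`.
    """
    return Hamming1Matcher(tags, max_mismatch).match(candidate)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read the sample-tag manifest, rejecting duplicate multiplex tags."""
    mani = pd.read_csv(path, sep="\t", dtype={"multiplex_tag": str})
    missing = set(MANIFEST_COLUMNS) - set(mani.columns)
    if missing:
        raise ConfigurationError(f"manifest missing columns: {sorted(missing)}")
    if mani["multiplex_tag"].duplicated().any():
        dups = mani.loc[mani["multiplex_tag"].duplicated(), "multiplex_tag"].tolist()
        raise ConfigurationError(f"duplicate multiplex tags in manifest: {dups}")
    bad_len = mani.loc[mani["multiplex_tag"].str.len() != 5, "multiplex_tag"].tolist()
    if bad_len:
        raise ConfigurationError(f"multiplex tags must be 5 nt: {bad_len}")
    return mani


def load_reference(path: str | Path) -> pd.DataFrame:
    ref = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("strain_id", "up_tag", "down_tag"):
        if col not in ref.columns:
            raise ConfigurationError(f"reference table missing column {col!r}")
    return ref


def demultiplex(read: str, tag_map: dict[str, int]) -> tuple[int | None, str]:
    """Assign a read to a sample by exact 5-nt prefix match (zero mismatches).

    Returns (sample index or None, read with the tag prefix removed).
    """
    prefix = read[:5]
    return tag_map.get(prefix), read[5:]


def trim_primer(read: str, primer5: str, primer3: str, barcode_len: int) -> str | None:
    """Extract the strain barcode from a demultiplexed, fixed-layout read.

    The 5' primer must match exactly at offset 0 and the read must be long
    enough to hold the barcode; the 3' flank is not checked (it carries no
    information and may be truncated by the read length).  Returns None when
    the layout does not match.
    """
    if not read.startswith(primer5):
        return None
    bc = read[len(primer5) : len(primer5) + barcode_len]
    if len(bc) < barcode_len:
        return None
    return bc


@dataclass
class SampleTally:
    total: int = 0
    assigned: int = 0
    ambiguous: int = 0
    unmatched: int = 0  # primer not found, wrong length, or no barcode within 1 mismatch


@dataclass
class CountingResult:
    counts: pd.DataFrame
    qc: pd.DataFrame
    unassigned: int = 0
    total_reads: int = 0

    def check_accounting(self) -> None:
        assigned = int(self.qc["assigned"].sum())
        ambiguous = int(self.qc["ambiguous"].sum())
        unmatched = int(self.qc["unmatched"].sum())
        if assigned + ambiguous + unmatched + self.unassigned != self.total_reads:
            raise AssertionError("read accounting identity violated")


def _open_maybe_gz(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(path: str | Path) -> Iterator[str]:
    with _open_maybe_gz(path) as fh:
        record_no = 0
        try:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                record_no += 1
                yield seq
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record after record {record_no} in {path}: {exc}") from exc


def count_reads(
    fastq_paths: str | Path | Iterable[str | Path],
    manifest: pd.DataFrame,
    reference: pd.DataFrame,
    max_mismatch: int = 1,
    barcode_len: int = 20,
) -> CountingResult:
    """Stream FASTQ file(s) into a CountTable plus per-sample QC tallies.

    Order-independent and additive: counting the concatenation of two files
    equals the sum of counting each.  The barcode position of a read is
    identified by which position's 5' primer matches the fixed layout, and
    the barcode is then matched within that position's tag class.
    """
    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]

    tag_map = {t: i for i, t in enumerate(manifest["multiplex_tag"])}
    if len(tag_map) != len(manifest):
        raise ConfigurationError("duplicate multiplex tags in manifest")
    matchers = {
        "B1": Hamming1Matcher(zip(reference["up_tag"], reference["strain_id"]), max_mismatch),
        "B2": Hamming1Matcher(zip(reference["down_tag"], reference["strain_id"]), max_mismatch),
    }
    primer_items = [(pos, PRIMERS[pos][0]) for pos in BARCODE_POSITIONS]

    tallies: dict[int, SampleTally] = {i: SampleTally() for i in tag_map.values()}
    counts: dict[tuple[int, str, str], int] = {}
    unassigned = 0
    total = 0

    for path in fastq_paths:
        for seq in _iter_fastq(path):
            total += 1
            sample, rest = demultiplex(seq, tag_map)
            if sample is None:
                unassigned += 1
                continue
            tally = tallies[sample]
            tally.total += 1
            strain = None
            for pos, primer5 in primer_items:
                bc = trim_primer(rest, primer5, "", barcode_len)
                if bc is None:
                    continue
                strain = matchers[pos].match(bc)
                break
            else:
                tally.unmatched += 1
                continue
            if strain is None:
                tally.unmatched += 1
            elif strain == AMBIGUOUS:
                tally.ambiguous += 1
            else:
                tally.assigned += 1
                key = (sample, pos, strain)
                counts[key] = counts.get(key, 0) + 1

    rows = []
    meta = manifest.reset_index(drop=True)
    for (sample, pos, strain), c in counts.items():
        m = meta.iloc[sample]
        rows.append(
            {
                "strain_id": strain,
                "barcode_position": pos,
                "pool": m["pool"],
                "background": m["background"],
                "condition": m["condition"],
                "bio_rep": m["bio_rep"],
                "tech_rep": m["tech_rep"],
                "timepoint_index": m["timepoint_index"],
                "generations": m["generations"],
                "count": c,
            }
        )
    count_df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    if len(count_df):
        count_df = count_df.sort_values(COUNT_COLUMNS[:9]).reset_index(drop=True)

    qc_rows = []
    for i, tally in tallies.items():
        m = meta.iloc[i]
        qc_rows.append(
            {
                "multiplex_tag": m["multiplex_tag"],
                "pool": m["pool"],
                "condition": m["condition"],
                "bio_rep": m["bio_rep"],
                "tech_rep": m["tech_rep"],
                "timepoint_index": m["timepoint_index"],
                "total": tally.total,
                "assigned": tally.assigned,
                "ambiguous": tally.ambiguous,
                "unmatched": tally.unmatched,
            }
        )
    qc = pd.DataFrame(qc_rows)

    result = CountingResult(counts=count_df, qc=qc, unassigned=unassigned, total_reads=total)
    result.check_accounting()
    return result
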