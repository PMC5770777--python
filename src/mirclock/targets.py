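"""Canonical seed-match target-site prediction.

The seed is miRNA positions 2-8 (5'->3').  Sites are scanned on the
target's sense strand only:

* 8mer    -- reverse-complement match to positions 2-8 followed by an A
             (opposite miRNA position 1);
* 7mer-m8 -- match to positions 2-8 without the trailing A;
* 7mer-A1 -- match to positions 2-7 plus the A;
* 6mer    -- match to positions 2-7 alone.

Each matched position is counted once under the most specific applicable
type.  Coordinates are 0-based half-open on the supplied sequence.  U and
T are equivalent.
"""

from __future__ import annotations

import re

import pandas as pd

from mirclock.exceptions import ConfigurationError

SITE_TYPES = ["8mer", "7mer-m8", "7mer-A1", "6mer"]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = re.compile(r"^[ACGTU]*$")


def _norm(seq: str, what: str) -> str:
    seq = seq.upper().replace("U", "T")
    if not _VALID.match(seq):
        bad = sorted(set(seq) - set("ACGTU"))
        raise ConfigurationError(f"invalid characters in {what}: {bad}")
    return seq


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seed_sites(mirna_seq: str, target_seq: str) -> pd.DataFrame:
    """All seed-match sites of one miRNA in one target sequence.

    Returns a frame with columns ``site_type``, ``start``, ``end`` (0-based
    half-open, covering the full site including the m8 match and/or the A).
    """
    mir = _norm(mirna_seq, "miRNA sequence")
    tgt = _norm(target_seq, "target sequence")
    if len(mir) < 8:
        raise ConfigurationError("miRNA must be at least 8 nt to define a seed")
    m8 = mir[7]  # position 8
    rc6 = revcomp(mir[1:7])  # reverse complement of positions 2-7
    m8_comp = m8.translate(_COMPLEMENT)

    rows = []
    for i in range(len(tgt) - 5):
        if tgt[i : i + 6] != rc6:
            continue
        has_m8 = i > 0 and tgt[i - 1] == m8_comp
        has_a1 = i + 6 < len(tgt) and tgt[i + 6] == "A"
        if has_m8 and has_a1:
            rows.append(("8mer", i - 1, i + 7))
        elif has_m8:
            rows.append(("7mer-m8", i - 1, i + 6))
        elif has_a1:
            rows.append(("7mer-A1", i, i + 7))
        else:
            rows.append(("6mer", i, i + 6))
    return pd.DataFrame(rows, columns=["site_type", "start", "end"])


def seed_site_report(
    mirna_seqs: dict[str, str], region_seqs: dict[str, str]
) -> pd.DataFrame:
    """Per (miRNA, transcript, region) site-type counts over FASTA-style
    dicts; region keys follow the ``transcript|region`` header convention."""
    rows = []
    for mir, mseq in mirna_seqs.items():
        for key, tseq in region_seqs.items():
            transcript, _, region = key.partition("|")
            sites = seed_sites(mseq, tseq)
            if len(sites) == 0:
                continue
            counts = sites["site_type"].value_counts()
            rows.append(
                {
                    "mirna_id": mir,
                    "transcript": transcript,
                    "region": region or "NA",
                    **{t: int(counts.get(t, 0)) for t in SITE_TYPES},
                    "total": int(len(sites)),
                }
            )
    cols = ["mirna_id", "transcript", "region", *SITE_TYPES, "total"]
    return pd.DataFrame(rows, columns=cols)


def predicted_targets(report: pd.DataFrame, min_sites: int = 1) -> set[tuple[str, str]]:
    """(miRNA, transcript) pairs with at least ``min_sites`` seed sites in
    any region -- the aggregation used to call a pair a predicted target."""
    agg = report.groupby(["mirna_id", "transcript"])["total"].sum()
    return set(agg.index[agg >= min_sites])
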