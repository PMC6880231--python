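"""Packaged reference tables from the published study being reproduced.

Four tables are shipped as plain CSV, transcribed from the published report
of a 30-participant mobile attention-bias-modification feasibility study:
per-participant session-wise bias scores with missingness annotations,
demographic counts by baseline-bias group, and substance-use histories of
the positive- and absent-bias groups.  Transcription notes: en-dash minus
signs were normalised to ASCII; participant ids are kept as printed (they
skip 025); footnote letters are carried verbatim in a ``footnotes`` column.

Each file is checksummed at load time so silent corruption of the packaged
data fails loudly rather than producing subtly wrong reproductions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .records import MissingReason, ParticipantTimeline, SessionSlot

_CHECKSUMS = {
    "table1_timelines.csv": "17db794e35359eddd4dda26870bc7934a0df816544ac480ec52fae3f24422216",
    "table2_demographics.csv": "020d5bf02b65d5695030b199e4ecc6ba04cd1cd0034c011d4fdce1f22cca53ca",
    "table2_numeric.csv": "4b6e64c6dae44debe2ca76059ed22b7acc23dea4b4b9ab154d5c1390b49d9526",
    "chisquare_printed.csv": "f7fd2ca32ca22b97676f082b2afeb3e9ff459cf38e454dc40564593449c5e67d",
    "table3_positive_history.csv": "a2d06b2f8c509050f7c9de24588035cff47c4cf04ec1c3680e71e0bca9b360ad",
    "table4_negative_history.csv": "462ae4234805ab57c74c3ed1146d4aa5fd54f75fa5500ff9f4cd5e087081970f",
}

N_SESSIONS = 5


class FixtureChecksumError(RuntimeError):
    """A packaged data file does not match its recorded checksum."""


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("probebias.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureChecksumError(
            f"packaged fixture {name} is corrupted: sha256 {digest} != "
            f"{_CHECKSUMS[name]}"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), dtype={"participant": str})


@dataclass
class PaperFixtures:
    """The packaged study tables.

    ``table1``: 30 rows; baseline + 5 post-session bias scores (ms), missing
    slots with reason codes, printed overall-change magnitude and direction.
    ``table2``: demographic level counts per baseline-bias group.
    ``table2_numeric``: printed mean (SD) of age and dependence-severity score.
    ``chisquare_printed``: the published chi-square battery (statistic, df, p)
    with a flag marking the values reproducible from ``table2``'s counts.
    ``table3`` / ``table4``: substance-use histories of the 14 positive- and
    16 absent-bias participants.
    """

    table1: pd.DataFrame
    table2: pd.DataFrame
    table2_numeric: pd.DataFrame
    chisquare_printed: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame

    def timelines(self) -> list[ParticipantTimeline]:
        """The 30 participants' session timelines as scoring-layer objects."""
        out = []
        for _, row in self.table1.iterrows():
            slots = []
            for i in range(1, N_SESSIONS + 1):
                val = row[f"post{i}"]
                if pd.isna(val):
                    slots.append(
                        SessionSlot(reason=MissingReason(row[f"reason{i}"]))
                    )
                else:
                    slots.append(SessionSlot(bias_ms=float(val)))
            out.append(
                ParticipantTimeline(
                    participant_id=str(row["participant"]),
                    baseline_bias_ms=float(row["baseline"]),
                    post_sessions=slots,
                )
            )
        return out


def load_fixtures() -> PaperFixtures:
    """Load and checksum-verify all packaged tables."""
    fx = PaperFixtures(
        table1=_read("table1_timelines.csv"),
        table2=_read("table2_demographics.csv"),
        table2_numeric=_read("table2_numeric.csv"),
        chisquare_printed=_read("chisquare_printed.csv"),
        table3=_read("table3_positive_history.csv"),
        table4=_read("table4_negative_history.csv"),
    )
    if len(fx.table1) != 30:
        raise FixtureChecksumError("table1 must have 30 participants")
    if len(fx.table3) != 14 or len(fx.table4) != 16:
        raise FixtureChecksumError("tables 3/4 must have 14 and 16 rows")
    return fx


def table2_contingency_counts(table2: pd.DataFrame) -> dict[str, "pd.DataFrame"]:
    """Per-factor 2×C count frames (rows positive/absent) from the table-2 fixture."""
    out = {}
    for factor, sub in table2.groupby("factor", sort=False):
        out[factor] = pd.DataFrame(
            {
                "level": sub["level"].tolist(),
                "positive": sub["positive_n"].tolist(),
                "absent": sub["negative_n"].tolist(),
            }
        )
    return out
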