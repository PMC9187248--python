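"""Packaged worked-example datasets.

Two fixtures describe the same 17-project integrated-care portfolio
evaluated in Queensland, Australia:

* :func:`load_league_fixture` — the published league table: the five
  criterion scores as printed (fractions rounded to one decimal place),
  the equal-weight total, net cost (AUD) and cost per point, one row per
  project, sorted by ascending cost per point.

* :func:`load_evidence_fixture` — a SYNTHETIC evidence-level reconstruction
  of the portfolio: per-criterion evidence records whose rubric scores
  reproduce the league-table score columns exactly and whose portfolio
  aggregates match the published counts (six capacity-significant projects;
  integration domain tallies of 9 clinical, 14+3 professional, 8+1
  organisational full/partial; eleven projects with workforce development;
  four projects at risk score 2 and one at 0). The per-project evidence
  composition is otherwise one of many consistent assignments — it is
  reconstructed, not original study data — and is frozen so golden tests
  stay stable.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .projects import ProjectRecord, load_projects

FIXTURE_VERSION = "1.0"

_LEAGUE_FILE = "league_table.csv"
_EVIDENCE_FILE = "evidence_fixture.json"

# frozen digests of the packaged fixture files (fixture version 1.0)
_SHA256 = {
    _LEAGUE_FILE: "210bb52c55efb26097685a52155f091725c35141858c95eaa614d5aed0b7ecd3",
    _EVIDENCE_FILE: "b965c9722f5337c4dd27b25ee1e00848d2f1725f078660c22366654fa1ee43f8",
}


def _read_packaged(name: str) -> bytes:
    data = (resources.files("caremcda") / "data" / name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _SHA256[name]:
        raise RuntimeError(
            f"packaged fixture {name} is corrupted: sha256 {digest} does not "
            f"match the frozen digest for fixture version {FIXTURE_VERSION}"
        )
    return data


def load_league_fixture() -> pd.DataFrame:
    """The published 17-row league table (checksum-verified).

    Columns: ``project_id``, the five criterion scores as printed,
    ``total``, ``net_cost`` and ``cost_per_point`` (AUD).
    """
    import io

    df = pd.read_csv(io.BytesIO(_read_packaged(_LEAGUE_FILE)), dtype={"project_id": str})
    if len(df) != 17:
        raise RuntimeError(f"league fixture must have 17 rows, found {len(df)}")
    return df


def load_evidence_fixture() -> list[ProjectRecord]:
    """The synthetic evidence-level reconstruction (17 validated records)."""
    import tempfile
    from pathlib import Path

    data = _read_packaged(_EVIDENCE_FILE)
    with tempfile.TemporaryDirectory() as tmp:
        path = Path(tmp) / _EVIDENCE_FILE
        path.write_bytes(data)
        records = load_projects(path)
    if len(records) != 17:
        raise RuntimeError(f"evidence fixture must have 17 records, found {len(records)}")
    return records
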