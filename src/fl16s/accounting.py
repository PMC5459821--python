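"""Per-sample read accounting.

Tracks read counts through the pipeline stages and summarises a
sample-accounting table (total / minimum / maximum / truncated mean of the
processed-read column).  A bundled table carries the published per-sample
CCS and processed (chimera- and length-filtered) read counts of the
18-sample, six-site coral survey the pipeline mirrors; it drives the
examples and the acceptance report without any sequence downloads.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["load_survey_read_counts", "summarize_read_counts"]


def load_survey_read_counts() -> pd.DataFrame:
    """Bundled 18-sample accounting table (group, site, sample, read counts)."""
    with resources.as_file(
        resources.files("fl16s").joinpath("data/survey_read_counts.tsv")
    ) as path:
        return read_accounting_table(path)


def read_accounting_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "n_processed_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"accounting table missing columns: {sorted(missing)}")
    return df


def summarize_read_counts(df: pd.DataFrame, column: str = "n_processed_reads") -> dict:
    """Column totals of a sample-accounting table.

    ``mean_truncated`` is the arithmetic mean truncated toward zero, the
    convention used when quoting whole-read averages.
    """
    counts = df[column].astype(int)
    if counts.empty:
        raise ValueError("empty accounting table")
    return {
        "n_samples": int(counts.size),
        "total": int(counts.sum()),
        "minimum": int(counts.min()),
        "maximum": int(counts.max()),
        "mean_truncated": int(counts.sum() // counts.size),
    }
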