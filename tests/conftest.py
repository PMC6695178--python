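"""Shared fixtures: flat-file entry builder and small synthetic proteomes."""

from __future__ import annotations

import textwrap

import pytest

from tmscape import SyntheticConfig, compute_f
from tmscape.synthetic_data import generate_proteome


def make_flatfile_entry(
    entry_id: str,
    sequence: str,
    spans,
    pe: int = 1,
    lineage=("Eukaryota", "Metazoa"),
    location: str = "Multi-pass membrane protein",
    notes=None,
) -> str:
    """Render one UniProt-style flat-file entry (new FT coordinate syntax)."""
    notes = notes or ["Helical"] * len(spans)
    lines = [
        f"ID   {entry_id:<24}Reviewed;        {len(sequence)} AA.",
        f"AC   {entry_id};",
        f"OC   {'; '.join(lineage)}.",
        f"PE   {pe}: Evidence at protein level;",
        f"CC   -!- SUBCELLULAR LOCATION: Membrane; {location}.",
    ]
    for (start, end), note in zip(spans, notes):
        lines.append(f"FT   TRANSMEM        {start}..{end}")
        lines.append(f'FT                   /note="{note}"')
    lines.append(
        f"SQ   SEQUENCE   {len(sequence)} AA;  {len(sequence) * 110} MW;  0000000000000000 CRC64;"
    )
    for chunk_start in range(0, len(sequence), 60):
        chunk = sequence[chunk_start : chunk_start + 60]
        blocks = " ".join(chunk[i : i + 10] for i in range(0, len(chunk), 10))
        lines.append(f"     {blocks}")
    lines.append("//")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=101, n_distribution={1: 20, 2: 40, 3: 30, 4: 20})


@pytest.fixture(scope="session")
def small_proteome(small_config):
    return generate_proteome(small_config)


@pytest.fixture(scope="session")
def small_table(small_proteome):
    return compute_f(small_proteome, n_max=19)
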