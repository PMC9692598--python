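"""Canonical descriptor registry.

Every module refers to descriptors by the canonical names defined here.
Sixteen calculated descriptors plus the chromatographic retention
descriptor ``log_kw_iam`` make up the modelling variable pool; the
remaining names are bookkeeping columns (identity, reference BCF values,
inputs to the classical log Kow screening models).
"""

from __future__ import annotations

# The 16 calculated molecular descriptors, in registry order.
# Units: Mw g/mol; HvAt/ArHvAt/FRB/HD/HA counts; F_Csp3 fraction in [0,1];
# MR and the dipole descriptors on the scale of the originating software;
# TPSA Angstrom^2; Et hartree; EHOMO/ELUMO eV; logKow dimensionless.
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "Mw",
    "HvAt",
    "ArHvAt",
    "F_Csp3",
    "FRB",
    "HD",
    "HA",
    "MR",
    "TPSA",
    "Et",
    "EHOMO",
    "ELUMO",
    "DipPCh",
    "DipH",
    "DipS",
    "logKow",
)

# Retention descriptor + 16 calculated descriptors: the variable pool used
# for regression modelling, in the order correlation tables are laid out.
MODEL_VARIABLES: tuple[str, ...] = ("log_kw_iam",) + DESCRIPTOR_NAMES

# Descriptors that are integer counts by definition.
COUNT_DESCRIPTORS: frozenset[str] = frozenset({"HvAt", "ArHvAt", "FRB", "HD", "HA"})

# Full canonical column set for compound tables.
TABLE_COLUMNS: tuple[str, ...] = (
    ("id", "name", "log_kw_iam")
    + DESCRIPTOR_NAMES
    + ("molar_volume", "ionic", "sum_F", "log_bcf_epi", "log_bcf_vivo")
)


def is_canonical(name: str) -> bool:
    """True if *name* is a canonical descriptor or table column."""
    return name in TABLE_COLUMNS
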