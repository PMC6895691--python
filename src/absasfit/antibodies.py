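"""IgG domain knowledge used across the package.

Hinge peptide sequences are given in EU numbering.  The human IgG1 hinge is
23 residues long and the IgG4 hinge 20; both carry two inter-heavy-chain
disulphides at Cys226 and Cys229.  These sequences define the flexible
regions varied by the Monte Carlo simulation designs and the reconstruction
targets for incomplete crystal structures.
"""

from __future__ import annotations

# --- IgG1 ------------------------------------------------------------------
# Upper hinge varied when the Cys226-Cys226 bridge is kept fixed (sim1)
IGG1_UPPER_HINGE = "CDKTHT"                       # EU 220-225
# Upper+middle+lower hinge used for symmetric randomisation
IGG1_FULL_HINGE = "CDKTHTCPPCPAPELLGGP"           # EU 220-238
# Full flexible stretch varied in the unconstrained/constrained designs
IGG1_SIM_HINGE = "VEPKSCDKTHTCPPCPAPELLGGP"       # EU 215-238
IGG1_HINGE_LENGTH = 23

# --- IgG4 ------------------------------------------------------------------
IGG4_UPPER_HINGE = "VESKYGPPC"                    # EU 212-220
# Hinge peptide rebuilt when assembling the starting model from separate
# Fab and Fc structures
IGG4_REBUILT_HINGE = "ESKYGPPCPSCPAPEFLGGP"       # EU 216-238
IGG4_SIM_HINGE = "VESKYGPPCPSCPAPEFLGGP"          # EU 215-238
IGG4_HINGE_LENGTH = 20

# Canonical inter-heavy-chain disulphide positions (EU numbering)
HINGE_CYS_EU = (226, 229)

# Segments absent from the full-length IgG1 b12 crystal structure (1HZH)
# that must be rebuilt before modelling: a CH1 loop, part of one hinge and
# one C-terminus.
MISSING_1HZH_SEGMENTS = {
    "CH1 132-138": "SKSTSGG",
    "hinge 223-225": "THT",
    "CH3 445-447": "PGL",
}


def missing_residue_count(segments: dict[str, str] | None = None) -> int:
    """Total residues across the rebuilt segments."""
    segments = segments if segments is not None else MISSING_1HZH_SEGMENTS
    return sum(len(s) for s in segments.values())
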