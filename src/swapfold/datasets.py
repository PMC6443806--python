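"""Published reference measurements for the FoxP1 forkhead domain.

These are the experimental kinetic and thermodynamic tables for the
wild-type protein and its H59A mutant at 37 degC (310 K): dissociation
constants (K_d), dissociation free energies (ΔG_d), dissociation and
association rates, and equilibrium unfolding parameters from linear
free-energy extrapolation. They are inputs for the worked examples and
the pH-linkage analyses; rates are per minute, concentrations molar,
energies kcal/mol.
"""

from __future__ import annotations

import numpy as np

#: pH values of the kinetic series (wild type; the mutant was measured at
#: 5.0, 6.0 and 7.8 only).
KINETICS_PH = np.array([5.0, 5.5, 6.0, 7.0, 7.8])

#: Kinetic/thermodynamic dissociation table, wild type.
#: Columns: K_d (M), ΔG_d (kcal/mol), k_off (min^-1), k_on (M^-1 min^-1);
#: *_sd are one-sigma uncertainties on the same scale.
WT_KINETICS = {
    "ph": KINETICS_PH,
    "k_d": np.array([31.2e-6, 13.1e-6, 3.7e-6, 0.8e-6, 0.6e-6]),
    "k_d_sd": np.array([0.3e-6, 0.2e-6, 0.3e-6, 0.1e-6, 0.1e-6]),
    "dg_d": np.array([6.4, 6.9, 7.7, 8.6, 8.8]),
    "dg_d_sd": np.array([0.1, 0.1, 0.1, 0.1, 0.1]),
    "k_off": np.array([140.9e-3, 40.5e-3, 33.2e-3, 68.1e-3, 63.8e-3]),
    "k_off_sd": np.array([9.5e-3, 4.0e-3, 3.8e-3, 7.2e-3, 5.1e-3]),
    "k_on": np.array([3.5e3, 3.1e3, 9.0e3, 80.2e3, 107.5e3]),
    "k_on_sd": np.array([0.7e3, 0.7e3, 1.6e3, 16.4e3, 13.5e3]),
}

#: Same table for the H59A mutant (pH 5.0, 6.0, 7.8).
H59A_KINETICS = {
    "ph": np.array([5.0, 6.0, 7.8]),
    "k_d": np.array([7.9e-6, 5.9e-6, 7.5e-6]),
    "k_d_sd": np.array([0.1e-6, 0.1e-6, 0.2e-6]),
    "dg_d": np.array([7.2, 7.4, 7.2]),
    "dg_d_sd": np.array([0.1, 0.1, 0.2]),
    "k_off": np.array([59.3e-3, 37.7e-3, 43.4e-3]),
    "k_off_sd": np.array([3.5e-3, 1.8e-3, 2.5e-3]),
    "k_on": np.array([7.5e3, 6.4e3, 5.8e3]),
    "k_on_sd": np.array([0.8e3, 0.3e3, 0.5e3]),
}

#: Equilibrium unfolding of the wild type (intrinsic fluorescence, 15 uM),
#: fitted two-state I <-> U: ΔG_U (kcal/mol) and m (kcal/mol/M).
WT_UNFOLDING = {
    "ph": np.array([5.0, 5.5, 6.0, 7.0, 7.8]),
    "dg_u": np.array([6.1, 6.3, 6.9, 8.4, 8.9]),
    "dg_u_sd": np.array([0.5, 0.2, 0.5, 0.4, 0.4]),
    "m": np.array([1.7, 1.8, 2.0, 2.2, 2.3]),
    "m_sd": np.array([0.1, 0.1, 0.1, 0.1, 0.1]),
}

#: Equilibrium unfolding of H59A (15 uM), fitted three-state
#: N2 <-> 2I <-> 2U: first (dimer) and second (monomer) transitions.
H59A_UNFOLDING = {
    "ph": np.array([5.0, 6.0, 7.8]),
    "dg_1": np.array([7.9, 8.6, 8.2]),
    "dg_1_sd": np.array([0.9, 0.9, 1.2]),
    "m_1": np.array([3.0, 3.2, 3.0]),
    "m_1_sd": np.array([0.1, 0.2, 0.1]),
    "dg_2": np.array([5.0, 5.6, 6.0]),
    "dg_2_sd": np.array([0.4, 0.7, 1.0]),
    "m_2": np.array([1.4, 1.6, 1.8]),
    "m_2_sd": np.array([0.1, 0.2, 0.1]),
}

#: Local (anisotropy) unfolding of labelled helices, three-state monomer
#: N <-> I <-> U at 0.1 uM: S57C reports helix H3, V78C helix H5.
S57C_UNFOLDING = {
    "ph": np.array([5.0, 7.8]),
    "dg_1": np.array([2.0, 1.6]),
    "dg_1_sd": np.array([0.5, 0.4]),
    "m_1": np.array([3.2, 2.7]),
    "m_1_sd": np.array([1.1, 0.6]),
    "dg_2": np.array([6.9, 10.4]),
    "dg_2_sd": np.array([0.8, 1.1]),
    "m_2": np.array([1.4, 2.0]),
    "m_2_sd": np.array([0.2, 0.4]),
}

V78C_UNFOLDING = {
    "ph": np.array([5.0, 7.8]),
    "dg_1": np.array([1.4, 0.6]),
    "dg_1_sd": np.array([0.3, 0.1]),
    "m_1": np.array([3.1, 5.0]),
    "m_1_sd": np.array([0.5, 0.9]),
    "dg_2": np.array([4.2, 4.7]),
    "dg_2_sd": np.array([0.2, 0.5]),
    "m_2": np.array([1.1, 1.1]),
    "m_2_sd": np.array([0.1, 0.1]),
}

#: Reported pKa values from the proton-linkage analyses.
REPORTED_PKA = {
    # association barrier analysis (monomer / transition state / dimer)
    "H59_barrier": {"monomer": 7.3, "ts": 5.5, "dimer": 5.5},
    "H54_barrier": 5.3,
    # unfolding analysis (intermediate / unfolded)
    "H54_unfolding": {"i": 5.3, "u": 5.9},
    "H59_unfolding": {"i": 5.7, "u": 7.7},
}
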