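"""Published ethanol reference values used as inputs.

Harmonic frequencies, torsional stationary-point energies and rotor moments
of inertia for trans/gauche ethanol, as printed in the source study of the
corrected coupled-cluster-quality surface.  These numbers are *inputs* here:
the package uses them to constrain the 2-D torsional model and to form
harmonic zero-point energies; it does not recompute the underlying
electronic structure.
"""

from __future__ import annotations

import numpy as np

from .torsion import CutConstraint, TorsionConstraint
from .units import AMU_TO_ME

# Harmonic frequencies (cm^-1) of the corrected surface, modes 1..21
ETHANOL_TRANS_FREQS_CM1 = np.array([
    243, 273, 417, 818, 909, 1055, 1115, 1181, 1284, 1302, 1403,
    1454, 1488, 1500, 1530, 2995, 3028, 3036, 3120, 3126, 3862,
], dtype=float)

ETHANOL_GAUCHE_FREQS_CM1 = np.array([
    268, 278, 424, 804, 894, 1075, 1094, 1144, 1290, 1375, 1406,
    1424, 1490, 1496, 1519, 3007, 3020, 3088, 3108, 3121, 3845,
], dtype=float)

# Corresponding directly computed coupled-cluster frequencies
ETHANOL_TRANS_FREQS_AB_INITIO_CM1 = np.array([
    222, 274, 413, 813, 907, 1049, 1115, 1180, 1274, 1300, 1402,
    1456, 1484, 1501, 1531, 3001, 3036, 3042, 3122, 3127, 3853,
], dtype=float)

ETHANOL_GAUCHE_FREQS_AB_INITIO_CM1 = np.array([
    258, 271, 420, 803, 895, 1069, 1096, 1141, 1284, 1374, 1402,
    1426, 1491, 1497, 1522, 3014, 3028, 3089, 3108, 3123, 3837,
], dtype=float)

# Electronic energies relative to the trans minimum (cm^-1)
ETHANOL_GAUCHE_MINIMUM_CM1 = 38.0       # gauche above trans
ETHANOL_TS1_ECLIPSED_CM1 = 377.0        # trans->gauche eclipsed saddle
ETHANOL_TS2_SYN_CM1 = 472.0             # syn saddle (hydroxyl over methyl)

# Methyl-torsion barriers (cm^-1) of the unrelaxed cuts at fixed OH angle
ETHANOL_METHYL_BARRIER_TRANS_CM1 = 1208.0
ETHANOL_METHYL_BARRIER_GAUCHE_CM1 = 1324.0
ETHANOL_METHYL_BARRIER_TS1_CM1 = 1283.0
ETHANOL_METHYL_BARRIER_TS2_CM1 = 1404.0

# Rotor moments of inertia (amu*bohr^2, i.e. the printed value/(N_AV m_e))
ETHANOL_I_OH_AMU_BOHR2 = 2.7
ETHANOL_I_CH3_AMU_BOHR2 = 10.5

ETHANOL_I_OH = ETHANOL_I_OH_AMU_BOHR2 * AMU_TO_ME      # m_e*bohr^2
ETHANOL_I_CH3 = ETHANOL_I_CH3_AMU_BOHR2 * AMU_TO_ME

# Experimental torsional term values relative to the lowest level (cm^-1)
ETHANOL_TORSION_LEVELS_EXP_CM1 = np.array(
    [0.0, 39.5, 42.8, 202.6, 238.6, 285.9, 244.4, 475.5, 529.49, 532.8])


def ethanol_torsion_constraints(gauche_methyl_shift_deg: float = 5.0):
    """Constraint set for the 2-D torsional model from the printed cuts.

    Angles: ``theta`` methyl torsion (trans-staggered at 0), ``phi``
    hydroxyl torsion (trans at 0, gauche at +-120 deg).  Energies are
    relative to the trans minimum.  The five constrained cuts are the
    methyl cuts at the trans, gauche, eclipsed-saddle and syn-saddle
    hydroxyl angles plus the hydroxyl cut at the trans methyl angle.

    ``gauche_methyl_shift_deg`` places the gauche methyl minimum at a small
    positive offset from the staggered angle (its mirror well sits at the
    opposite offset), which encodes the geared coupling of the two rotors;
    the printed cuts fix its energy but not its exact position.
    """
    g = ETHANOL_GAUCHE_MINIMUM_CM1
    shift = gauche_methyl_shift_deg
    return [
        # hydroxyl cut at the trans methyl angle
        CutConstraint("oh", 0.0, [
            (0.0, 0.0, ()),
            (60.0, ETHANOL_TS1_ECLIPSED_CM1, ("phi",)),
            (120.0, None, ("phi",)),
            (180.0, ETHANOL_TS2_SYN_CM1, ()),
        ]),
        # methyl cut at the trans hydroxyl angle
        CutConstraint("methyl", 0.0, [
            (60.0, ETHANOL_METHYL_BARRIER_TRANS_CM1, ()),
        ]),
        # methyl cut at the eclipsed-saddle hydroxyl angle
        CutConstraint("methyl", 60.0, [
            (0.0, None, ("theta",)),
            (60.0, ETHANOL_TS1_ECLIPSED_CM1 + ETHANOL_METHYL_BARRIER_TS1_CM1,
             ("theta",)),
        ]),
        # methyl cut at the syn-saddle hydroxyl angle
        CutConstraint("methyl", 180.0, [
            (60.0, ETHANOL_TS2_SYN_CM1 + ETHANOL_METHYL_BARRIER_TS2_CM1, ()),
        ]),
        # gauche well (2-D stationary) and its methyl barrier
        TorsionConstraint("value", shift, 120.0, g),
        TorsionConstraint("dtheta", shift, 120.0, 0.0),
        TorsionConstraint("dphi", shift, 120.0, 0.0),
        TorsionConstraint("value", shift + 60.0, 120.0,
                          g + ETHANOL_METHYL_BARRIER_GAUCHE_CM1),
        TorsionConstraint("dtheta", shift + 60.0, 120.0, 0.0),
    ]
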