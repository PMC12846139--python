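"""Default straight-line muscle geometry for the head–neck linkage.

The 72 cervical muscles (36 bilateral pairs) are modelled as straight
lines from origin to insertion.  Attachment coordinates are a documented
default geometry constructed for the reduced two-articulation chain: they
place each muscle in an anatomically sensible compartment (anterior hyoid
group, sternocleidomastoid group, scalenes, deep prevertebral flexors,
posterior extensors, suboccipitals) so that every muscle has a plausible
action, without claiming digitized-cadaver accuracy.

Coordinates are parametric in the chain dimensions:

* ``L1`` — lower cervical segment length (T1 to the mid-cervical joint), m
* ``L2`` — upper segment length (mid-cervical joint to skull base), m
* ``Wh`` — shoulder half-width (biacromial breadth / 2), m

Frames follow the torso convention: x anterior, y left, z superior.  The
table lists the RIGHT-side muscle of each pair (y <= 0 on the right); the
left partner (suffix ``_L``) is obtained by mirroring y -> -y.

Depth classes follow the anatomical split used by the weighted static
optimization: deep stabilizers (prevertebral flexors, semispinalis,
longissimus, iliocostalis, suboccipitals) vs. superficial movers
(sternocleidomastoid/trapezius groups, scalenes, splenius, hyoid chain).
The classification is a packaged default and can be overridden per model.
"""

from __future__ import annotations

DEEP = "deep"
SUP = "superficial"

# name: (origin_body, origin(L1, L2, Wh), insertion_body, insertion(L1, L2, Wh),
#        f_max N, depth class, origin scales with shoulder width)
# Bodies: "torso" (ground), "neck" (lower segment frame), "head" (upper frame;
# skull base sits at z = L2 in this frame).
MUSCLE_GEOMETRY = {
    # ---- anterior hyoid chain (superficial flexor sheet) ----
    "digastric_post": ("torso", lambda L1, L2, Wh: (0.050, -0.015, -0.010),
                       "head", lambda L1, L2, Wh: (0.030, -0.020, L2 - 0.010), 40.0, SUP, False),
    "digastric_ant": ("torso", lambda L1, L2, Wh: (0.060, -0.010, -0.010),
                      "head", lambda L1, L2, Wh: (0.075, -0.010, L2 - 0.015), 40.0, SUP, False),
    "Geniohyoid": ("torso", lambda L1, L2, Wh: (0.055, -0.008, -0.020),
                   "head", lambda L1, L2, Wh: (0.080, -0.008, L2 - 0.020), 35.0, SUP, False),
    "Mylohyoid_Post": ("torso", lambda L1, L2, Wh: (0.050, -0.012, -0.015),
                       "head", lambda L1, L2, Wh: (0.065, -0.020, L2 - 0.020), 30.0, SUP, False),
    "Mylohyoid_Ant": ("torso", lambda L1, L2, Wh: (0.055, -0.008, -0.020),
                      "head", lambda L1, L2, Wh: (0.075, -0.012, L2 - 0.025), 30.0, SUP, False),
    "Stylohyoid_Lat": ("torso", lambda L1, L2, Wh: (0.045, -0.020, -0.010),
                       "head", lambda L1, L2, Wh: (0.020, -0.030, L2 - 0.005), 25.0, SUP, False),
    "Stylohyoid_Med": ("torso", lambda L1, L2, Wh: (0.050, -0.012, -0.010),
                       "head", lambda L1, L2, Wh: (0.025, -0.020, L2 - 0.005), 25.0, SUP, False),
    "Sterno_hyoid": ("torso", lambda L1, L2, Wh: (0.055, -0.010, -0.050),
                     "head", lambda L1, L2, Wh: (0.070, -0.010, L2 - 0.030), 50.0, SUP, False),
    "SternoThyroid": ("torso", lambda L1, L2, Wh: (0.050, -0.012, -0.060),
                      "head", lambda L1, L2, Wh: (0.065, -0.015, L2 - 0.035), 50.0, SUP, False),
    "Omo_hyoid": ("torso", lambda L1, L2, Wh: (0.020, -0.85 * Wh, -0.030),
                  "head", lambda L1, L2, Wh: (0.060, -0.012, L2 - 0.030), 40.0, SUP, True),
    # ---- sternocleidomastoid group ----
    "stern_mast": ("torso", lambda L1, L2, Wh: (0.055, -0.020, -0.030),
                   "head", lambda L1, L2, Wh: (-0.015, -0.070, L2 + 0.000), 250.0, SUP, False),
    "cleid_mast": ("torso", lambda L1, L2, Wh: (0.030, -0.45 * Wh, -0.015),
                   "head", lambda L1, L2, Wh: (-0.015, -0.070, L2 + 0.000), 150.0, SUP, True),
    "cleid_occ": ("torso", lambda L1, L2, Wh: (0.025, -0.55 * Wh, -0.015),
                  "head", lambda L1, L2, Wh: (-0.050, -0.050, L2 + 0.010), 120.0, SUP, True),
    # ---- scalenes (lateral flexors, torso -> lower segment) ----
    "scalenus_ant": ("torso", lambda L1, L2, Wh: (0.040, -0.055, -0.060),
                     "neck", lambda L1, L2, Wh: (0.015, -0.030, 0.85 * L1), 120.0, SUP, False),
    "scalenus_med": ("torso", lambda L1, L2, Wh: (0.030, -0.070, -0.060),
                     "neck", lambda L1, L2, Wh: (0.000, -0.035, 0.90 * L1), 120.0, SUP, False),
    "scalenus_post": ("torso", lambda L1, L2, Wh: (0.015, -0.075, -0.070),
                      "neck", lambda L1, L2, Wh: (-0.010, -0.035, 0.80 * L1), 100.0, SUP, False),
    # ---- deep prevertebral flexors ----
    "long_cap_sklc4": ("neck", lambda L1, L2, Wh: (0.022, -0.012, 0.90 * L1),
                       "head", lambda L1, L2, Wh: (0.030, -0.012, L2 - 0.005), 180.0, DEEP, False),
    "long_col_c1thx": ("torso", lambda L1, L2, Wh: (0.022, -0.010, -0.040),
                       "head", lambda L1, L2, Wh: (0.028, -0.012, 0.75 * L2), 160.0, DEEP, False),
    "long_col_c1c5": ("neck", lambda L1, L2, Wh: (0.018, -0.012, 0.50 * L1),
                      "head", lambda L1, L2, Wh: (0.018, -0.012, 0.75 * L2), 80.0, DEEP, False),
    "long_col_c5thx": ("torso", lambda L1, L2, Wh: (0.020, -0.012, -0.030),
                       "neck", lambda L1, L2, Wh: (0.018, -0.012, 0.50 * L1), 50.0, DEEP, False),
    # ---- trapezius ----
    "trap_cl": ("torso", lambda L1, L2, Wh: (0.020, -0.60 * Wh, -0.020),
                "head", lambda L1, L2, Wh: (-0.055, -0.030, L2 + 0.015), 300.0, SUP, True),
    "trap_acr": ("torso", lambda L1, L2, Wh: (-0.020, -1.00 * Wh, -0.030),
                 "head", lambda L1, L2, Wh: (-0.060, -0.025, L2 + 0.010), 300.0, SUP, True),
    # ---- splenius ----
    "splen_cap_sklc6": ("neck", lambda L1, L2, Wh: (-0.025, -0.005, 0.30 * L1),
                        "head", lambda L1, L2, Wh: (-0.030, -0.050, L2 + 0.005), 180.0, SUP, False),
    "splen_cap_sklthx": ("torso", lambda L1, L2, Wh: (-0.035, -0.010, -0.050),
                         "head", lambda L1, L2, Wh: (-0.035, -0.055, L2 + 0.005), 180.0, SUP, False),
    "splen_cerv_c3thx": ("torso", lambda L1, L2, Wh: (-0.035, -0.008, -0.060),
                         "neck", lambda L1, L2, Wh: (-0.010, -0.035, 0.95 * L1), 120.0, SUP, False),
    # ---- semispinalis (deep extensors) ----
    "semi_cap_sklc5": ("neck", lambda L1, L2, Wh: (-0.025, -0.010, 0.40 * L1),
                       "head", lambda L1, L2, Wh: (-0.050, -0.020, L2 + 0.010), 150.0, DEEP, False),
    "semi_cap_sklthx": ("torso", lambda L1, L2, Wh: (-0.035, -0.015, -0.055),
                        "head", lambda L1, L2, Wh: (-0.050, -0.018, L2 + 0.010), 150.0, DEEP, False),
    "semi_cerv_c3thx": ("torso", lambda L1, L2, Wh: (-0.035, -0.012, -0.060),
                        "neck", lambda L1, L2, Wh: (-0.020, -0.015, 1.00 * L1), 100.0, DEEP, False),
    # ---- levator scapulae ----
    "levator_scap": ("torso", lambda L1, L2, Wh: (-0.040, -0.80 * Wh, -0.045),
                     "neck", lambda L1, L2, Wh: (-0.005, -0.035, 0.95 * L1), 200.0, SUP, True),
    # ---- longissimus / iliocostalis (deep lateral extensors) ----
    "longissi_cap_sklc6": ("neck", lambda L1, L2, Wh: (-0.020, -0.020, 0.30 * L1),
                           "head", lambda L1, L2, Wh: (-0.020, -0.065, L2 - 0.005), 90.0, DEEP, False),
    "longissi_cerv_c4thx": ("torso", lambda L1, L2, Wh: (-0.030, -0.025, -0.060),
                            "neck", lambda L1, L2, Wh: (0.000, -0.030, 1.00 * L1), 90.0, DEEP, False),
    "iliocost_cerv_c5rib": ("torso", lambda L1, L2, Wh: (-0.020, -0.060, -0.080),
                            "neck", lambda L1, L2, Wh: (-0.005, -0.035, 0.50 * L1), 80.0, DEEP, False),
    # ---- suboccipitals (deep, act across the upper articulation) ----
    "rectcap_post_maj": ("neck", lambda L1, L2, Wh: (-0.025, -0.010, 0.95 * L1),
                         "head", lambda L1, L2, Wh: (-0.045, -0.015, L2 + 0.005), 50.0, DEEP, False),
    "rectcap_post_min": ("neck", lambda L1, L2, Wh: (-0.020, -0.005, 1.00 * L1),
                         "head", lambda L1, L2, Wh: (-0.040, -0.008, L2 + 0.005), 40.0, DEEP, False),
    "obl_cap_sup": ("neck", lambda L1, L2, Wh: (-0.010, -0.030, 1.00 * L1),
                    "head", lambda L1, L2, Wh: (-0.040, -0.035, L2 + 0.005), 45.0, DEEP, False),
    "obl_cap_inf": ("neck", lambda L1, L2, Wh: (-0.025, -0.008, 0.90 * L1),
                    "head", lambda L1, L2, Wh: (-0.010, -0.045, 0.80 * L2), 45.0, DEEP, False),
}

BASE_MUSCLE_NAMES = list(MUSCLE_GEOMETRY)  # 36 right-side names; "_L" = left partner

#: Functionally spanning 8-pair subset used for desk-scale runs: mixes
#: deep/superficial classes and flexor/extensor/lateral/rotator actions.
REDUCED_MUSCLE_SET = [
    "stern_mast",
    "trap_cl",
    "splen_cap_sklthx",
    "semi_cap_sklc5",
    "long_cap_sklc4",
    "long_col_c1thx",
    "scalenus_med",
    "levator_scap",
]
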