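"""Reference lifetimes (ns) of the NIR antibody probe in different compartments.

These values are used throughout the package as simulation defaults and as
the fixed basis lifetimes of the dual-exponential decay model. All times in
nanoseconds.
"""

#: Free dye in solution.
FREE_DYE_FLT_NS = 0.41

#: Antibody-dye conjugate in solution.
CONJUGATE_FLT_NS = 0.54

#: Intracellular probe in cultured tumor cells.
INTRACELLULAR_FLT_NS = 0.66

#: Whole-animal wide-field imaging, tumor region (specific basis, tau_T).
IN_VIVO_TUMOR_FLT_NS = 0.80

#: Whole-animal wide-field imaging, surrounding normal tissue (tau_NS).
IN_VIVO_NORMAL_FLT_NS = 0.70

#: Open-abdomen (in situ) imaging of deep liver tumors, tumor region.
IN_SITU_TUMOR_FLT_NS = 0.85

#: Open-abdomen imaging, normal liver.
IN_SITU_LIVER_FLT_NS = 0.60

#: Confocal microscopy of tissue sections, per-region mean lifetimes.
MICRO_TUMOR_FLT_NS = 1.04
MICRO_MUSCLE_FLT_NS = 0.75
MICRO_VESSEL_FLT_NS = 0.49
MICRO_ADIPOSE_FLT_NS = 0.79
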