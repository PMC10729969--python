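"""Unit conventions and conversion constants.

The canonical internal unit system is cells/ml for population density,
micromolar (μM) for dissolved sulfide, and hours for time.  Per-cell
sulfide quantities are expressed in femtomoles (1 fmole = 1e-15 mole);
1 fmole/ml of dissolved sulfide equals 1e-6 μM.
"""

#: Cell density corresponding to one OD600 unit on the reference
#: instrument (13-mm glass tubes on a tube spectrophotometer).
CELLS_PER_OD: float = 7e7

#: Conversion from fmole/ml to μM: 1 fmole/ml = 1e-15 mol / 1e-3 l = 1e-12 M.
UM_PER_FMOLE_PER_ML: float = 1e-6

#: OD600 readings below this are indistinguishable from blank and are
#: clamped to it.
OD_SENSITIVITY_FLOOR: float = 0.001

#: OD600 above which turbidity no longer scales linearly with cell density.
OD_LINEAR_LIMIT: float = 0.5
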