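"""Ion ranges and emission-energy reconstruction.

The monitor's transport layer answers two questions: how deep does the
primary beam stop (the quantity being monitored), and how much energy did a
detected fragment have at emission (needed for particle identification and
absorption modelling)?
"""

from fragmon.transport import (
    CARBON12,
    PMMA,
    PROTON,
    WATER,
    csda_range,
    invert_energy_loss,
    transport_energy,
)

depth = csda_range(CARBON12, 220.0, PMMA)
print(f"220 MeV/u carbon in PMMA stops at {depth:.2f} cm "
      "-- the Bragg peak the monitor tracks.")

for e in (95.0, 150.0, 220.0):
    print(f"  carbon {e:6.1f} MeV/u: range {csda_range(CARBON12, e, PMMA):5.2f} cm PMMA, "
          f"{csda_range(CARBON12, e, WATER):5.2f} cm water")

e_det = 60.0
e_emit = invert_energy_loss(PROTON, e_det, 2.0, PMMA)
print(f"\nA secondary proton detected at {e_det:.0f} MeV after a 2.0 cm PMMA "
      f"exit path was emitted at {e_emit:.1f} MeV.")
check = transport_energy(PROTON, e_emit, 2.0, PMMA)
print(f"Forward check: transporting {e_emit:.1f} MeV through the same path "
      f"leaves {check:.1f} MeV.")
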