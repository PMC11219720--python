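"""Simulate the three-group hemorrhage-resuscitation cohort.

15 subjects (3 fluid groups x 5), 180-min protocol: 1 L bled over the
first hour, then 1 L of the group's fluid mix in each of two 60-min
resuscitation phases.  Impedance is sampled every 3 min at 6 frequencies
in 5 segments; vitals every minute.  Raw tables go to scratch/cohort/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import GROUPS, SCRATCH, load_cohort


def main() -> None:
    impedance, vitals = load_cohort()
    print(f"cohort written under {SCRATCH}")
    print(f"impedance rows: {len(impedance)} "
          f"({impedance.subject_id.nunique()} subjects x 61 times x 5 segments x 6 freqs)")
    print(f"vitals rows:    {len(vitals)}")
    n_missing = int(vitals["map"].isna().sum())
    print(f"vitals rows with undetectable MAP: {n_missing} "
          "(arterial waveform lost at deep hypovolemia)")
    for group in GROUPS:
        sub = impedance[impedance.subject_id.str.startswith(group + "_")]
        torso5 = sub[(sub.segment == "torso") & (sub.frequency_khz == 5.0)]
        by_t = torso5.groupby("t_min")["z_ohm"].mean()
        print(f"{group:22s} torso |Z(5kHz)| baseline {by_t.iloc[0]:6.1f} ohm, "
              f"peak {by_t.max():6.1f} at t={by_t.idxmax():.0f} min, "
              f"end {by_t.iloc[-1]:6.1f} ohm")


if __name__ == "__main__":
    main()
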