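"""Censor high-motion volumes and apply the 4-minute inclusion rule.

Volumes with frame-to-frame translation > 1 mm or rotation > 1.5 degrees
are removed together with the immediately preceding frame; a scan must
keep at least 4 minutes of data (80 volumes at TR 3 s) to stay in the
analysis.
"""

from fetalcwas import motion, synthetic

spec = synthetic.CohortSpec(
    n_subjects=6, n_rois=10, n_modules=2, n_volumes=110,
    motion_spike_prob=0.10, seed=7,
)
cohort = synthetic.generate_cohort(spec)

print(f"{'scan':<10}{'spikes':>7}{'retained':>9}{'minutes':>9}  included")
for scan in cohort.scans:
    spikes = int(((abs(scan.translation_delta) > 1.0)
                  | (abs(scan.rotation_delta) > 1.5)).sum())
    motion.censor_motion(scan)
    motion.censor_mad(scan)
    ok = motion.check_inclusion(scan)
    print(f"{scan.scan_id:<10}{spikes:>7}{scan.retained_volumes:>9}"
          f"{scan.retained_minutes:>9.2f}  {ok}")

print("\nEach spike removes up to 2 volumes (itself plus the preceding "
      "frame); a scan drops below the line when fewer than 80 volumes "
      "(4 min x 60 s / 3 s) survive.")
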