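"""Spatial-object-recognition metrics for a test session.

Preference % = T_novel / (T_familiar + T_novel) x 100;
discrimination ratio = (T_novel - T_familiar) / (T_familiar + T_novel).
Sessions with under 2 s of total exploration are excluded.
"""

from murisleep import sor_metrics

for t_novel, t_familiar in [(30.0, 10.0), (10.0, 10.0), (0.5, 1.0)]:
    res = sor_metrics(t_novel, t_familiar)
    print(f"novel {t_novel:5.1f} s, familiar {t_familiar:5.1f} s -> "
          f"preference {res.preference_pct:5.1f} %, "
          f"discrimination {res.discrimination_ratio:+.2f}, "
          f"excluded: {res.excluded}")
# 75 % / +0.5 marks intact spatial memory; 50 % / 0 is chance.
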