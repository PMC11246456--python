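# Miniature synthetic stand-in for the EMA Important Medical Events list:
# cardiac terms only, enough to drive tests and the worked example.
# Not the official EMA list (which is versioned with MedDRA and licensed).
Bradycardia
Cardiac arrest
Atrioventricular block
Atrial fibrillation
Atrioventricular block complete
Arrhythmia
Sinus bradycardia
Atrioventricular block second degree
Ventricular tachycardia
Sinus node dysfunction
Ventricular fibrillation
Sinus arrest
Atrioventricular block first degree
Atrial flutter
Sinoatrial block
Conduction disorder
Torsade de pointes
Cardiogenic shock
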