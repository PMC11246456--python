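# Cardiac adverse reactions already carried on the target drug's label;
# signals absent from this list are flagged as novel.  Miniature fixture
# list assembled for the lacosamide worked example.
Bradycardia
Cardiac arrest
Atrioventricular block
Atrial fibrillation
Atrioventricular block complete
Cardio-respiratory arrest
Arrhythmia
Sinus bradycardia
Atrioventricular block second degree
Ventricular tachycardia
Atrioventricular block first degree
Atrial flutter
Conduction disorder
Palpitations
Tachycardia
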