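pt,n,ror025,deaths,importance,evidence,published_score,published_level
Bradycardia,135,4.94,4,IME,++,6,moderate
Cardiac arrest,80,1.92,23,IME,++,6,moderate
Atrioventricular block,67,16.80,8,IME,++,7,moderate
Atrial fibrillation,67,1.21,2,IME,+,4,weak
Atrioventricular block complete,58,17.23,5,IME,++,7,moderate
Cardio-respiratory arrest,39,1.68,27,NA,+,4,weak
Arrhythmia,34,1.22,3,IME,++,4,weak
Sinus bradycardia,29,5.07,0,IME,++,6,moderate
Atrioventricular block second degree,27,15.19,1,IME,++,5,moderate
Ventricular tachycardia,26,2.92,2,IME,++,5,moderate
Sinus node dysfunction,19,10.10,1,IME,++,6,moderate
Ventricular fibrillation,15,2.16,4,DME,++,7,moderate
Sinus arrest,14,14.13,0,IME,++,6,moderate
Atrioventricular block first degree,14,4.52,3,IME,++,5,moderate
Atrial flutter,14,2.35,0,IME,++,5,moderate
Sinoatrial block,5,8.57,0,IME,++,5,moderate
Conduction disorder,5,3.12,0,IME,++,4,weak
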