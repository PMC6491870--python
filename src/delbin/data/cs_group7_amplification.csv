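line,P1,P2,P3,P4,P5,P6
CS Dt7AS,+,+,+,+,-,+
CS Dt7AL,+,+,-,-,+,+
CS Dt7BS,+,+,+,+,+,-
CS Dt7BL,+,+,+,+,+,+
CS Dt7DS,+,+,+,+,+,+
CS Dt7DL,-,-,+,+,+,+
CS Del7AS-1,+,+,+,+,+,+
CS Del7AS-2,+,+,-,-,+,+
CS Del7AS-3,+,+,-,-,+,+
CS Del7AS-4,+,+,-,-,+,+
CS Del7AS-5,+,+,-,-,+,+
CS Del7AS-6,+,+,-,-,+,+
CS Del7AS-7,+,+,+,+,+,+
CS Del7AS-11,+,+,-,-,+,+
CS Del7AS-8,+,+,-,-,+,+
CS Del7AS-12,+,+,+,+,+,+
CS Del7AL-1,+,+,+,+,-,+
CS Del7AL-2,+,+,+,+,+,+
CS Del7AL-4,+,+,+,+,-,+
CS Del7AL-6,+,+,+,+,+,+
CS Del7AL-7,+,+,+,+,-,+
CS Del7AL-8,+,+,+,+,+,+
CS Del7AL-9,+,+,+,+,+,+
CS Del7AL-10,+,+,+,+,+,+
CS Del7AL-11,+,+,+,+,-,+
CS Del7AL-14,+,+,+,+,-,+
CS Del7AL-15,+,+,+,+,+,+
CS Del7AL-16,+,+,+,+,+,+
CS Del7AL-17,+,+,+,+,+,+
CS Del7AL-18,+,+,+,+,+,+
CS Del7AL-20,+,+,+,+,+,+
CS Del7AL-21,+,+,+,+,+,+
CS Del7BL-1,+,+,+,+,+,-
CS Del7BL-2,+,+,+,+,+,-
CS Del7BL-3,+,+,+,+,+,+
CS Del7BL-4,+,+,+,+,+,+
CS Del7BL-5,+,+,+,+,+,+
CS Del7BL-6,+,+,+,+,+,+
CS Del7BL-7,+,+,+,+,+,+
CS Del7BL-12,+,+,+,+,+,-
CS Del7BL-13,+,+,+,+,+,+
CS Del7DS-1,-,-,+,+,+,+
CS Del7DS-4,-,-,+,+,+,+
CS Del7DS-5,-,-,+,+,+,+
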