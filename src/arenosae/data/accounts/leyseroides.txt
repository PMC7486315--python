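5.0–35.0 cm tall, spreading or rarely erect. Stem pubescent in lower part, more or less glabrous with sessile glands in upper part; with 3–5 distinct internodes, the uppermost internode (1.0–)2.0–3.0(–4.0) cm long and obviously longer than the next upper internode. Basal leaves oblanceolate or lanceolate 10.0–30.0 × 1.0–3.0 mm, pubescent, scabrous. Cauline leaves linear or lanceolate 20.0–35.0 × 2.0–3.0 mm, pubescent, scabrous. Calyx (8.0–)9.0–13.0(–14.0) mm long, cylindrical at anthesis and clavate in fruit, rarely glabrous, or pubescent; teeth unequal; shorter ones 1.0–2.0 mm, lanceolate, acuminate; longer ones 2.0–3.0(–4.0) mm, lanceolate, acuminate; marginal hairs long (longer than 0.5 mm), dense. Inflorescence divaricate, branch axile usually > 90°. Petal claws 6.0–7.0 mm long, glabrous; limbs 4.0–7.0 mm long, bifid, upper-surface pink, lobes linear, divergent, petal limbs cleft to middle or more, lower-surface carmine or green; coronal scales 0.8–1.1 mm long, ovate, apex entire or slightly dentate. Anthophore (4.0–) 5.0–7.0 mm long, densely puberulent. Anthers exserted; filaments 7.0–8.0 mm long, glabrous. Styles exserted. First pedicel 1.0–3.0 cm in flower, 2.0–4.0 cm in fruit, spreading, glabrous, apex usually geniculate, or antrorse. Capsule 6.0–8.0 mm long, oblong or ellipsoid, fragile, opaque. Seeds 0.6–0.9 mm wide, 0.4–0.6 mm high, testa smooth.
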