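15.0–60.0 cm tall, erect or rarely spreading. Stem pubescent in lower part, scabrous, glabrous but with sessile glands in upper part; with 4–12 distinct internodes, the uppermost internode (2.0–)3.0–8.0(–10.0) cm long and obviously longer than the next upper internode. Basal leaves oblanceolate, pubescent. Cauline leaves linear or oblanceolate 10.0–50.0 × 2.0–6.0 mm, pubescent, scabrous. Calyx 13.0–17.0 mm long, ovoid at anthesis and clavate in fruit, scabrous; teeth unequal; shorter ones 2.0–4.0 mm, lanceolate, acuminate; longer ones 4.0–7.0 mm, lanceolate, acuminate; marginal hairs long (longer than 0.5 mm), dense. Inflorescence non-divaricate, branch axile (much) less than 90°. Petal claws 7.0–8.0 mm long, glabrous; limbs 5.0–8.0 mm long, bifid, upper-surface pink, lobes oblong, petal limbs cleft to middle or more; coronal scales 1.0–1.5 mm long, ovate, apex dentate. Anthophore 4.0–6.0 mm long, densely puberulent. Anthers included; filaments 8.0–9.0 mm long, glabrous. Styles exserted or included. First pedicel 1.0–4.0 cm in flower, 2.0–6.0 cm in fruit, erect, glabrous, apex antrorse. Capsule 7.0–11.0 mm long, oblong or ellipsoid, robust. Seeds ca 1.1 mm wide, ca. 0.7 mm high, testa smooth.
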