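20.0–40.0 cm tall, erect or spreading. Stem pubescent in lower part, more or less glabrous but with sessile glands in upper part; with 10–20 distinct internodes, the uppermost internode 2.0–4.0 cm long and equal to the next upper internode. Cauline leaves oblanceolate 10.0–30.0 × 1.0–2.0 mm, pubescent. Calyx 12.0–13.0 mm long, campanulate at anthesis and clavate in fruit, pubescent, scabrous; teeth unequal; shorter ones 1.5–2.0 mm, lanceolate, acuminate; longer ones 2.0–2.5 mm, lanceolate, acuminate; marginal hairs long (longer than 0.5 mm), dense. Inflorescence non-divaricate, branch axile (much) less than 90°. Petal claws 6.0–7.0 mm long, ciliate; limbs 4.0–5.0 mm long, bifid, upper-surface white or pink, lobes oblong, petal limbs cleft to middle or more; coronal scales ovate, apex dentate or erose. Anthophore 5.0–6.0 mm long, densely puberulent. Anthers included; filaments 6.0–7.0 mm long, glabrous or pubescent. Styles included. First pedicel 0.5–1.0 cm in flower, and 1.0 cm in fruit, erect, glabrous, apex antrorse. Capsule 7.0 mm long, oblong, fragile, opaque. Seeds 0.7–0.9 mm wide, 0.7 mm high, testa smooth.
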