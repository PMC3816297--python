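<?xml version="1.0" encoding="UTF-8"?>
<!-- Schema for provgraph workflow-execution account documents.
     One document per workflow execution; collections are serialised as
     <entity> elements carrying a size attribute greater than 1. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="qualified">

  <xs:element name="account">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="project-ref" minOccurs="0">
          <xs:complexType>
            <xs:attribute name="id" type="xs:string" use="required"/>
            <xs:attribute name="name" type="xs:string" use="required"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="agents">
          <xs:complexType>
            <xs:sequence>
              <xs:element ref="agent" minOccurs="0" maxOccurs="unbounded"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="activities">
          <xs:complexType>
            <xs:sequence>
              <xs:element ref="activity" minOccurs="0" maxOccurs="unbounded"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="entities">
          <xs:complexType>
            <xs:sequence>
              <xs:element ref="entity" minOccurs="0" maxOccurs="unbounded"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="relations">
          <xs:complexType>
            <xs:sequence>
              <xs:element ref="relation" minOccurs="0" maxOccurs="unbounded"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="annotations" type="annotationList"/>
        <xs:element name="recorded-violations" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="violation" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="element" type="xs:string"
                                minOccurs="1" maxOccurs="unbounded"/>
                  </xs:sequence>
                  <xs:attribute name="axis" type="xs:string" use="required"/>
                  <xs:attribute name="rule" type="xs:string" use="required"/>
                  <xs:attribute name="message" type="xs:string"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="id" type="xs:string" use="required"/>
      <xs:attribute name="name" type="xs:string" use="required"/>
      <xs:attribute name="description" type="xs:string"/>
      <xs:attribute name="location" type="xs:string"/>
      <xs:attribute name="execution_date" type="xs:string"/>
      <xs:attribute name="version" type="xs:positiveInteger" use="required"/>
      <xs:attribute name="version_date" type="xs:string"/>
      <xs:attribute name="start_time" type="xs:string"/>
      <xs:attribute name="end_time" type="xs:string"/>
      <xs:attribute name="notes" type="xs:string"/>
    </xs:complexType>
  </xs:element>

  <xs:complexType name="annotationList">
    <xs:sequence>
      <xs:element name="annotation" minOccurs="0" maxOccurs="unbounded">
        <xs:complexType>
          <xs:simpleContent>
            <xs:extension base="xs:string">
              <xs:attribute name="key" type="xs:string" use="required"/>
            </xs:extension>
          </xs:simpleContent>
        </xs:complexType>
      </xs:element>
    </xs:sequence>
  </xs:complexType>

  <xs:group name="nodeChildren">
    <xs:sequence>
      <xs:element name="group" type="xs:string" minOccurs="0" maxOccurs="unbounded"/>
      <xs:element name="annotation" minOccurs="0" maxOccurs="unbounded">
        <xs:complexType>
          <xs:simpleContent>
            <xs:extension base="xs:string">
              <xs:attribute name="key" type="xs:string" use="required"/>
            </xs:extension>
          </xs:simpleContent>
        </xs:complexType>
      </xs:element>
    </xs:sequence>
  </xs:group>

  <xs:element name="agent">
    <xs:complexType>
      <xs:group ref="nodeChildren"/>
      <xs:attribute name="id" type="xs:string" use="required"/>
      <xs:attribute name="name" type="xs:string" use="required"/>
      <xs:attribute name="institution" type="xs:string"/>
      <xs:attribute name="position" type="xs:string"/>
      <xs:attribute name="function" type="xs:string"/>
      <xs:attribute name="notes" type="xs:string"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="activity">
    <xs:complexType>
      <xs:group ref="nodeChildren"/>
      <xs:attribute name="id" type="xs:string" use="required"/>
      <xs:attribute name="name" type="xs:string" use="required"/>
      <xs:attribute name="program" type="xs:string"/>
      <xs:attribute name="program_version" type="xs:string"/>
      <xs:attribute name="command_line" type="xs:string"/>
      <xs:attribute name="function" type="xs:string"/>
      <xs:attribute name="start_time" type="xs:string"/>
      <xs:attribute name="end_time" type="xs:string"/>
      <xs:attribute name="environment" type="xs:string"/>
      <xs:attribute name="notes" type="xs:string"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="entity">
    <xs:complexType>
      <xs:group ref="nodeChildren"/>
      <xs:attribute name="id" type="xs:string" use="required"/>
      <xs:attribute name="name" type="xs:string" use="required"/>
      <xs:attribute name="description" type="xs:string"/>
      <xs:attribute name="location" type="xs:string"/>
      <xs:attribute name="notes" type="xs:string"/>
      <!-- presence of size (> 1) marks a collection -->
      <xs:attribute name="size" type="xs:positiveInteger"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="relation">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="annotation" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:simpleContent>
              <xs:extension base="xs:string">
                <xs:attribute name="key" type="xs:string" use="required"/>
              </xs:extension>
            </xs:simpleContent>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="id" type="xs:string" use="required"/>
      <xs:attribute name="kind" use="required">
        <xs:simpleType>
          <xs:restriction base="xs:string">
            <xs:enumeration value="used"/>
            <xs:enumeration value="wasGeneratedBy"/>
            <xs:enumeration value="wasAssociatedWith"/>
            <xs:enumeration value="wasDerivedFrom"/>
            <xs:enumeration value="memberOf"/>
          </xs:restriction>
        </xs:simpleType>
      </xs:attribute>
      <xs:attribute name="source" type="xs:string" use="required"/>
      <xs:attribute name="target" type="xs:string" use="required"/>
      <xs:attribute name="role" type="xs:string"/>
      <xs:attribute name="derivation_type">
        <xs:simpleType>
          <xs:restriction base="xs:string">
            <xs:enumeration value="filtering"/>
            <xs:enumeration value="ordering"/>
            <xs:enumeration value="mixing"/>
            <xs:enumeration value="other"/>
          </xs:restriction>
        </xs:simpleType>
      </xs:attribute>
      <xs:attribute name="auto_derived" type="xs:boolean" use="required"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
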